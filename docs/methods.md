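# Methods

## Mapper construction

The cover of the lens range `[lo, hi]` consists of `t` equal-length
intervals of length `L = (hi − lo) / (t − (t−1)p)`, interval `i` starting
at `lo + i·L·(1−p)`, so consecutive intervals share exactly `p·L` and the
union tiles the range exactly (for `[0,1]`, `t = 4`, `p = 0.2` this gives
the four intervals of length 5/17 used as the package's exactness check).
The lens range is taken as the min/max of the observed lens values; a
zero-width range is padded by 1e−9 per side. Intervals are closed on both
ends, so a sample sitting exactly on a shared boundary belongs to both
intervals — the choice that maximises consistency with the overlap
semantics. Nerve edges are found via a sample-to-vertex inverted index over
*all* vertex pairs, not only adjacent intervals: at `p > 0.5` non-adjacent
intervals intersect, and restricting the scan would silently drop edges.

Pullback clustering is pluggable. The agglomerative option (scikit-learn,
Ward/complete/average/single linkage, fixed cluster count `k`) caps `k` at
the preimage size, so tiny preimages yield singleton-capable clusters
rather than errors. The density option wraps scikit-learn's HDBSCAN;
points labelled noise are dropped from the graph (standard density
semantics), and `allow_single_cluster` is enabled by default because a
Mapper preimage frequently *is* a single cluster, which stock HDBSCAN
would otherwise discard wholesale as noise. Vertex ids are assigned in
(interval index, cluster label) order, making repeated runs bit-identical.

Duplicate vertices (identical member sets arising from overlapping
intervals) are kept distinct: they carry different interval tags and the
downstream statistics count unique samples anyway.

## Lens sampling

A lens is `f(x) = Σ αᵢ xᵢ` with the nonzero count drawn uniformly from
`[1, floor(max_nonzero_frac · n)]` (default fraction 0.5), nonzero
positions a uniform subset, and values uniform on [−2.5, 2.5]. The
uniform-count rule is the simplest distribution consistent with an
"at most half nonzero" constraint; nothing in the method depends on the
particular sparsity law beyond reproducibility. Streams of candidate
lenses derive per-lens seeds from `SeedSequence([master_seed, index])`, so
a search is replayable from one integer. A pre-selection hook restricts
the nonzero positions to a user-supplied feature subset. Externally
computed lens values (PCA, UMAP, or any per-sample score) can be fed
directly to `build_mapper`; the package does not recompute them.

## Community detection

Single linkage under the edge gradient `F'` is implemented as Kruskal's
minimum-spanning-forest construction: graph-restricted single linkage and
the MSF are the same algorithm, and the union-find form is O(E log E)
instead of O(V³). Vertices in different graph components never merge
(infinite distance). The cut threshold τ is the midpoint of the largest
gap between consecutive *distinct* merge heights; ties between equally
large gaps resolve to the lowest gap, which yields the smallest — most
conservative — communities. If there are fewer than two distinct heights
there is nothing to cut and each graph component is one community. By
default the gap analysis pools the merge heights of the whole forest;
`per_component=True` cuts each component at its own largest gap instead,
which matters when components live on different gradient scales.

## Community classification

`S(C)` counts *unique* samples: Mapper's overlap duplicates samples across
vertices, and the size thresholds are meant in patients, not memberships.
σ₂ is the unnormalised median absolute deviation (no 1.4826 consistency
constant) of all community sizes. The neighbourhood mean `Â(N_C)` is the
unweighted mean of `Â` over neighbourhood vertices — each vertex counts
once regardless of its size — with a member-count-weighted alternative
available (`weighted_neighbourhood=True`). The gap test is directional:
`direction="high"` demands `Â(C) − Â(N_C) > ε` (the default, matching a
search for elevated event rates), `"low"` the negative gap, `"both"` the
absolute value. With fewer than two communities classification is
degenerate — there is no neighbourhood — and every record is rejected.
Samples captured by no vertex (density-clustering noise) are excluded from
all counts.

## Ranking

Within one lens, hotspots from all `(t, p)` covers are pooled before
ranking. Two rankings are provided:

* `attr_enrichment` scores a hotspot by the Dice agreement between its
  sample set and the cohort's attribute mass,
  `2 Σ_{x∈C} A(x) / (S(C) + Σ_x A(x))`. For a binary class label this is
  1 exactly when the hotspot contains every positive sample and nothing
  else. A one-sided score (the captured share alone, or within-hotspot
  purity alone) systematically prefers either diluted or truncated
  communities; the symmetric score was chosen because the benchmark task
  asks for a hotspot that is simultaneously complete and clean.
* `logrank` scores by the p-value of the two-group log-rank test of the
  hotspot's survival against all other graph-captured samples; only
  hotspots with `p < α` count as successes.

Ties resolve by log-rank p, then smaller `t`, then smaller `p`, then
vertex-id order. Lens-level stopping is the default (the first successful
lens ends the search); `stop_on_success=False` keeps collecting across the
full lens budget for collective analysis.

A caveat inherent to the method: selecting parameters *because* they
produce a significant hotspot is a multiple-testing exercise — the
reported log-rank p-values are selection-biased and should be treated as
ranking scores, not calibrated error rates. The permutation check in the
test suite (shuffled attributes almost never revalidate) probes exactly
this.

## Survival statistics

Log-rank (unstratified, 1 df) and Kaplan-Meier estimation are delegated to
lifelines. Records are administratively censored at the analysis horizon
(default 120 months, i.e. 10-year relapse-free survival) before testing,
and the binary attribute fed to hotspot detection is "event observed
strictly before the horizon". With zero events in both groups the log-rank
statistic is undefined; the comparison returns p = 1 with a degenerate
flag rather than raising. Canberra distance (`Σ|x−y|/(|x|+|y|)`, zero-zero
terms contribute 0) scores validation-cohort samples against a discovery
hotspot's centroid restricted to the lens's nonzero features; it is
deliberately sensitive near zero, suiting deviation-from-healthy z-scores.

## Synthetic fixtures

`generate_two_circles` emulates the classic two-concentric-rings benchmark:
5000 points split evenly between rings of radius 1.0 and 0.5, uniform in
angle with radial Gaussian noise (σ = 0.03), and a contiguous arc of the
outer ring — exactly `round(0.081 · n)` = 405 points, assigned by angular
order so the count is exact — labelled Class 1. Radii, noise and arc
placement are the package's own defaults (the benchmark is defined by its
class fraction and ring structure, not by particular radii), which is why
the recovery checks are tolerance-banded rather than exact.

`generate_survival_fixture` plants a small high-hazard cluster: Gaussian
clusters (default sizes 40/700/700, unit noise, centres `separation = 6`
apart on coordinate axes) with exponential event times, the designated
cluster's hazard multiplied by 6 over a baseline of −ln(0.65)/120 per
month (≈ 35 % ten-year background event probability, resembling an ER+
relapse cohort), and independent exponential censoring (0.002/month). It
emulates the *statistical* structure of a cohort hiding a poor-prognosis
subgroup — cluster separation, event-rate contrast, censoring — but not
the correlation structure, batch effects or preprocessing of real
expression data, so passing tests demonstrate the algorithm's mechanics,
not robustness to real-data noise.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full search at the
benchmark scale: 5000 samples for the two-circles experiment (cover grid
{5,10,15,20,25} × {40 %, 60 %, 80 %}, Ward `k = 6`, σ₁ = 30, ε = 0.5,
five seeds) and 1440 samples for the survival experiment (grid
{10,15,20} × {30 %, 40 %}, Ward `k = 4`, σ₁ = 30, ε = 0.1, α = 0.05,
twenty seeds). The log-rank null calibration uses 2000 replicates of
n = 50-per-group exponential draws, keeping the Monte-Carlo standard error
of the rejection-rate estimate near 0.5 %. Floating-point tie-breaks are
everywhere resolved toward the lexically smallest option (lowest gap,
smallest vertex id, smallest `t` then `p`) so that identical inputs give
identical outputs across platforms.

## Known limitations

* Only 1-D lenses are implemented; a 2-D cover (overlap per axis) would
  require grid-cover semantics the method itself never exercises.
* Clustering settings are fixed configuration, not searched.
* No multiplicity correction is applied across the parameter grid; see the
  selection-bias caveat above.
* The largest-gap cut assumes the gradient distribution is bimodal enough
  to have a meaningful gap; on graphs whose edge gradients vary smoothly
  the cut degenerates to one community per component (and classification
  then rejects everything as degenerate — a correct, if silent, outcome).
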