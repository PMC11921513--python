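# tdahotspot

Hotspot detection in Mapper graphs for patient subgroup discovery.

`tdahotspot` is for researchers who suspect that a *small* group of samples
— a poor-prognosis patient subset, a rare phenotype — hides inside a larger
cohort of tabular omics data (gene-expression z-scores, proteomics, any
samples × features matrix), and who want both the subgroup and the Mapper
parameters that reveal it found automatically.

## The method

The Mapper algorithm summarises a point cloud `X ⊂ R^n` as a graph: a lens
function `f : X → R` projects the data onto the line, the range of `f(X)`
is covered with `t` equal-length intervals overlapping on a fraction `p` of
their length, a clustering algorithm runs on each interval's preimage
`f⁻¹(I)` *in the original feature space*, and each cluster becomes a graph
vertex, with an edge wherever two clusters share a sample.

On top of that graph, a **hotspot** is a small, connected, internally
homogeneous community of vertices whose attribute values differ sharply
from the rest of the graph. Given a per-sample attribute `A` (a relapse
indicator, a class label, any real value):

1. every vertex `v` gets the mean attribute `Â(v) = (1/|v|) Σ_{x∈v} A(x)`;
2. every edge gets the gradient weight `F'(u,v) = |Â(u) − Â(v)|`;
3. single-linkage clustering of the vertices under `F'` (non-adjacent
   vertices are at infinite distance) is cut at the largest gap between
   consecutive merge heights, yielding attribute-homogeneous communities;
4. a community `C` is a hotspot when its unique-sample size satisfies
   `S(C) ≥ σ₁`, its neighbourhood `N_C` (all other vertices) is larger by
   more than `σ₂` = the median absolute deviation of all community sizes,
   and the attribute gap `Â(C) − Â(N_C)` exceeds a user threshold `ε` in
   the requested direction.

The central idea is to turn Mapper parameter selection on its head: instead
of hand-tuning the lens and the cover, the search samples random sparse
linear lenses `f(x) = Σ αᵢ xᵢ` (each `αᵢ` either zero or uniform on
[−2.5, 2.5], at most half nonzero), builds a graph for every `(t, p)` pair
of a grid, and keeps the first lens whose graphs contain a hotspot. The
domain thresholds `σ₁` and `ε` — intuitive for a clinician — replace the
opaque Mapper parameters. With survival data, candidate hotspots are ranked
by the log-rank p-value of hotspot vs neighbourhood relapse-free survival.

## Worked example

Everything below runs offline: the package generates its own benchmark, two
concentric rings of 5000 points where 8.1 % of the samples (n = 405) form a
contiguous arc of the outer ring labelled Class 1.

```python
import tdahotspot as th

data, attr, truth = th.generate_two_circles(th.TwoCirclesSpec(seed=1))
result = th.search(
    data, attr, survival=None,
    grid=th.SearchGrid(interval_values=(5, 10, 15, 20, 25),
                       overlap_values=(0.4, 0.6, 0.8), max_lenses=20),
    hotspot_config=th.HotspotConfig(sigma1=30, epsilon=0.5, direction="high"),
    ranking=th.RankingSpec(method="attr_enrichment"),
    clusterer=th.ClustererSpec(method="agglomerative", n_clusters=6, linkage="ward"),
    master_seed=1, max_nonzero_frac=1.0,
)
best = result.best
truth_idx = {data.sample_ids.index(s) for s in truth}
cm = th.confusion_f1(best.record.community.sample_ids, truth_idx, data.n_samples)
print(f"t={best.t} p={best.p}  S={best.record.community.size}  "
      f"recall={cm['recall']:.3f}  f1={cm['f1']:.3f}")
```

Output:

```
t=20 p=0.4  S=394  recall=0.973  f1=0.986
```

The search accepted the first sampled lens, built one Mapper graph per
`(t, p)` pair, and the top-ranked hotspot — a community of 394 unique
samples found at 20 intervals with 40 % overlap — recovers 97.3 % of the
planted Class-1 arc with an F1 of 0.99 against the ground-truth labels.

The same pipeline is scriptable from the shell:

```sh
hotspot fixtures two-circles --n 5000 --seed 1 --out fix/
hotspot search --matrix fix/matrix.csv --attr fix/attribute.csv \
    --intervals 5,10,15,20,25 --overlaps 0.4,0.6,0.8 \
    --sigma1 30 --epsilon 0.5 --clusterer agglo --k 6 \
    --max-nonzero-frac 1.0 --seed 1 --out report.json --lens-out lens.json
```

and `hotspot revalidate --matrix other.csv --lens lens.json …` re-applies a
discovery lens verbatim to an independent cohort, varying only the cover.

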