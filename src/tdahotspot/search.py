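"""Joint search over lens functions and cover parameters.

Hotspot existence is the Mapper parameter-selection criterion: candidate
lenses are drawn from a reproducible stream, a Mapper graph is built for
every (t, p) pair of the cover grid, and hotspot detection is run on each
graph.  A lens "succeeds" when any of its graphs contains a hotspot (under
log-rank ranking, a hotspot whose survival split is significant); by
default the search stops at the first successful lens and returns its
hotspots ranked.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .hotspot import ClassificationRecord, HotspotConfig, detect_hotspots
from .lens import LensFunction, apply_lens, lens_stream
from .mapper import ClustererSpec, DataMatrix, MapperGraph, build_mapper
from .stats import SurvivalData, logrank_test

__all__ = [
    "SearchGrid",
    "RankingSpec",
    "HotspotReport",
    "SearchResult",
    "enumerate_grid",
    "search",
    "revalidate",
]


@dataclass(frozen=True)
class SearchGrid:
    """Cover-parameter grid plus the lens budget and stopping rule."""

    interval_values: tuple[int, ...]
    overlap_values: tuple[float, ...]
    max_lenses: int = 100
    stop_on_success: bool = True

    def __post_init__(self) -> None:
        if not self.interval_values or not self.overlap_values:
            raise ValueError("interval and overlap lists must be nonempty")
        if any(t < 1 for t in self.interval_values):
            raise ValueError("interval counts must be >= 1")
        if any(not (0.0 <= p < 1.0) for p in self.overlap_values):
            raise ValueError("overlaps must lie in [0, 1)")
        if self.max_lenses < 1:
            raise ValueError("max_lenses must be >= 1")
        object.__setattr__(self, "interval_values", tuple(int(t) for t in self.interval_values))
        object.__setattr__(self, "overlap_values", tuple(float(p) for p in self.overlap_values))


@dataclass(frozen=True)
class RankingSpec:
    """How pooled hotspots are ordered.

    ``attr_enrichment`` ranks by the Dice agreement between the hotspot's
    sample set and the cohort's attribute mass,
    ``2 * sum_{x in C} A(x) / (S(C) + sum_x A(x))``: for a binary class
    label this is 1 exactly when the hotspot contains all positive samples
    and nothing else, and it penalises both dilution (extra negatives) and
    truncation (missed positives).  ``logrank`` ranks by the log-rank
    p-value of hotspot vs neighbourhood survival; a hotspot only counts as
    a success when p < alpha.
    """

    method: str = "attr_enrichment"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.method not in ("attr_enrichment", "logrank"):
            raise ValueError(f"unknown ranking method {self.method!r}")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")


@dataclass(frozen=True)
class HotspotReport:
    """A classified hotspot plus the parameters and score that produced it."""

    record: ClassificationRecord
    lens: LensFunction
    lens_index: int
    t: int
    p: float
    sample_ids: frozenset[str]
    score: float
    logrank_p: float | None = None

    @property
    def sample_indices(self) -> frozenset[int]:
        return self.record.community.sample_ids


@dataclass(frozen=True)
class SearchResult:
    best: HotspotReport | None
    all_hits: tuple[HotspotReport, ...]
    lenses_tried: int
    graphs_built: int


def enumerate_grid(grid: SearchGrid) -> list[tuple[int, float]]:
    """Cartesian product of interval and overlap values, t-major order."""
    return list(itertools.product(grid.interval_values, grid.overlap_values))


def _rank_key(ranking: RankingSpec):
    def key(report: HotspotReport):
        primary = (
            report.logrank_p if ranking.method == "logrank" else -report.score
        )
        tie_p = report.logrank_p if report.logrank_p is not None else np.inf
        return (
            primary,
            tie_p,
            report.t,
            report.p,
            min(report.record.community.vertex_ids),
        )

    return key


def _score_hotspots(
    records: Sequence[ClassificationRecord],
    graph: MapperGraph,
    data: DataMatrix,
    attr: np.ndarray,
    survival: SurvivalData | None,
    ranking: RankingSpec,
    lens: LensFunction,
    lens_index: int,
    t: int,
    p: float,
) -> list[HotspotReport]:
    total_attr = float(attr.sum())
    reports = []
    for rec in records:
        if not rec.is_hotspot:
            continue
        inside = sorted(rec.community.sample_ids)
        denom = len(inside) + total_attr
        score = float(2.0 * attr[inside].sum() / denom) if denom > 0 else 0.0
        logrank_p = None
        if survival is not None:
            # neighbourhood = all other samples captured by the graph
            outside = sorted(graph.samples() - rec.community.sample_ids)
            if inside and outside:
                logrank_p = logrank_test(
                    survival.subset(inside), survival.subset(outside)
                ).p_value
        if ranking.method == "logrank":
            if logrank_p is None or logrank_p >= ranking.alpha:
                continue
            score = logrank_p
        reports.append(
            HotspotReport(
                record=rec,
                lens=lens,
                lens_index=lens_index,
                t=t,
                p=p,
                sample_ids=frozenset(data.sample_ids[i] for i in inside),
                score=score,
                logrank_p=logrank_p,
            )
        )
    return reports


def _search_lenses(
    data: DataMatrix,
    attr: np.ndarray,
    survival: SurvivalData | None,
    lenses: Iterable[tuple[int, LensFunction]],
    grid: SearchGrid,
    hotspot_config: HotspotConfig,
    ranking: RankingSpec,
    clusterer: ClustererSpec,
) -> SearchResult:
    attr = np.asarray(attr, dtype=float)
    if attr.shape != (data.n_samples,):
        raise ValueError("attribute length must match the sample count")
    if ranking.method == "logrank" and survival is None:
        raise ValueError("log-rank ranking requires survival records")
    pairs = enumerate_grid(grid)
    all_hits: list[HotspotReport] = []
    lenses_tried = 0
    graphs_built = 0
    for lens_index, lens in lenses:
        lenses_tried += 1
        lens_values = apply_lens(data, lens)
        lens_hits: list[HotspotReport] = []
        for t, p in pairs:
            graph = build_mapper(data, lens_values, t, p, clusterer)
            graphs_built += 1
            records = detect_hotspots(graph, attr, hotspot_config)
            lens_hits.extend(
                _score_hotspots(
                    records, graph, data, attr, survival, ranking,
                    lens, lens_index, t, p,
                )
            )
        all_hits.extend(lens_hits)
        if lens_hits and grid.stop_on_success:
            break
    all_hits.sort(key=_rank_key(ranking))
    return SearchResult(
        best=all_hits[0] if all_hits else None,
        all_hits=tuple(all_hits),
        lenses_tried=lenses_tried,
        graphs_built=graphs_built,
    )


def search(
    data: DataMatrix,
    attr: np.ndarray,
    survival: SurvivalData | None,
    grid: SearchGrid,
    hotspot_config: HotspotConfig,
    ranking: RankingSpec,
    clusterer: ClustererSpec,
    master_seed: int,
    max_nonzero_frac: float = 1.0,
    feature_subset: frozenset[int] | None = None,
) -> SearchResult:
    """Search lens functions and cover parameters for a hotspot.

    For each candidate lens (up to ``grid.max_lenses``) a Mapper graph is
    built for every (t, p) pair and hotspot detection runs on each graph;
    hotspots found for one lens are pooled across the grid before ranking.
    With ``stop_on_success`` the search ends at the first successful lens.
    Fully reproducible from ``master_seed``.
    """
    stream = lens_stream(
        data.n_features,
        master_seed=master_seed,
        max_nonzero_frac=max_nonzero_frac,
        feature_subset=feature_subset,
    )
    lenses = itertools.islice(enumerate(stream), grid.max_lenses)
    return _search_lenses(
        data, attr, survival, lenses, grid, hotspot_config, ranking, clusterer
    )


def revalidate(
    data: DataMatrix,
    attr: np.ndarray,
    survival: SurvivalData | None,
    fixed_lens: LensFunction,
    grid: SearchGrid,
    hotspot_config: HotspotConfig,
    ranking: RankingSpec,
    clusterer: ClustererSpec,
) -> SearchResult:
    """Re-run the cover search on an independent cohort with the lens held
    fixed: only (t, p) vary, mirroring validation of a discovered subgroup
    in a second dataset whose value ranges may differ."""
    if fixed_lens.n_features != data.n_features:
        raise ValueError(
            f"lens has {fixed_lens.n_features} coefficients for "
            f"{data.n_features} features"
        )
    return _search_lenses(
        data, attr, survival, [(0, fixed_lens)], grid, hotspot_config, ranking,
        clusterer,
    )
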