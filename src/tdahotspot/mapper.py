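"""Mapper graph construction.

The Mapper algorithm summarises a point cloud ``X ⊂ R^n`` as a graph: a
real-valued lens function stratifies the data into overlapping slabs
(preimages of an interval cover of the lens range), a conventional
clustering algorithm is run on each slab *in the original feature space*,
and the nerve of the resulting cluster collection is returned — one vertex
per cluster, one edge per pair of clusters sharing at least one sample.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.cluster import HDBSCAN, AgglomerativeClustering

__all__ = [
    "DataMatrix",
    "Interval",
    "CoverScheme",
    "MapperVertex",
    "MapperGraph",
    "ClustererSpec",
    "build_cover",
    "pullback_cluster",
    "build_nerve",
    "build_mapper",
]

#: symmetric pad applied to a zero-width lens range so the cover is well defined
_DEGENERATE_PAD = 1e-9


@dataclass(frozen=True)
class DataMatrix:
    """A samples-by-features real matrix with unique sample identifiers."""

    values: np.ndarray
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got shape {values.shape}")
        k, n = values.shape
        if k < 1 or n < 1:
            raise ValueError(f"matrix must be at least 1x1, got {k}x{n}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"missing/non-finite value at sample {bad[0]}, feature {bad[1]}"
            )
        ids = tuple(str(s) for s in self.sample_ids)
        if len(ids) != k:
            raise ValueError(f"{len(ids)} sample ids for {k} rows")
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Interval:
    """One member of the overlapping interval cover of the lens range."""

    lo: float
    hi: float
    index: int

    def contains(self, x: float | np.ndarray) -> np.ndarray:
        # closed on both ends: a point on a shared boundary belongs to both
        # neighbouring intervals, maximising overlap consistency
        return (np.asarray(x) >= self.lo) & (np.asarray(x) <= self.hi)


@dataclass(frozen=True)
class CoverScheme:
    """Cover parameters: ``t`` equal-length intervals overlapping by fraction ``p``."""

    t: int
    p: float
    lens_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.t < 1:
            raise ValueError(f"number of intervals t must be >= 1, got {self.t}")
        if not (0.0 <= self.p < 1.0):
            raise ValueError(f"overlap p must lie in [0, 1), got {self.p}")
        lo, hi = self.lens_range
        if lo > hi:
            raise ValueError(f"invalid lens range ({lo}, {hi})")

    @property
    def interval_length(self) -> float:
        lo, hi = self.lens_range
        return (hi - lo) / (self.t - (self.t - 1) * self.p)


def build_cover(lens_range: tuple[float, float], t: int, p: float) -> list[Interval]:
    """Cover ``lens_range`` with ``t`` equal intervals overlapping on fraction ``p``.

    The interval length is ``L = R / (t - (t-1)p)`` where ``R`` is the range
    width; interval ``i`` starts at ``lo + i·L·(1-p)``, so consecutive
    intervals share exactly ``p·L`` and the union tiles the range exactly.
    For ``R = [0,1]``, ``t=4``, ``p=0.2`` this gives four intervals of length
    5/17: [0,5/17], [4/17,9/17], [8/17,13/17], [12/17,1].
    """
    lo, hi = float(lens_range[0]), float(lens_range[1])
    if lo == hi:
        lo -= _DEGENERATE_PAD
        hi += _DEGENERATE_PAD
    scheme = CoverScheme(t=t, p=p, lens_range=(lo, hi))
    L = scheme.interval_length
    step = L * (1.0 - p)
    intervals = []
    for i in range(t):
        start = lo + i * step
        intervals.append(Interval(lo=start, hi=start + L, index=i))
    # anchor the last endpoint exactly to the range end
    last = intervals[-1]
    intervals[-1] = Interval(lo=last.lo, hi=hi, index=last.index)
    return intervals


@dataclass
class MapperVertex:
    """A cluster of sample indices found within one cover interval."""

    id: int
    members: frozenset[int]
    interval_index: int
    attr_mean: float | None = None

    def __post_init__(self) -> None:
        self.members = frozenset(int(m) for m in self.members)
        if not self.members:
            raise ValueError("vertex must have at least one member")


@dataclass
class MapperGraph:
    """Vertices (pullback clusters) plus the nerve edges between them.

    ``edges`` maps an ordered pair ``(u, v)`` with ``u < v`` to the edge's
    attribute-gradient weight ``|Â(u) - Â(v)|``, or ``None`` before the
    graph has been annotated with an attribute.
    """

    vertices: list[MapperVertex] = field(default_factory=list)
    edges: dict[tuple[int, int], float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [v.id for v in self.vertices]
        if len(set(ids)) != len(ids):
            raise ValueError("vertex ids must be unique")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def vertex(self, vid: int) -> MapperVertex:
        return self._by_id[vid]

    @property
    def _by_id(self) -> dict[int, MapperVertex]:
        return {v.id: v for v in self.vertices}

    def neighbors(self, vid: int) -> set[int]:
        out = set()
        for u, v in self.edges:
            if u == vid:
                out.add(v)
            elif v == vid:
                out.add(u)
        return out

    def samples(self) -> frozenset[int]:
        """All sample indices captured by at least one vertex."""
        out: set[int] = set()
        for v in self.vertices:
            out |= v.members
        return frozenset(out)

    def connected_components(self) -> list[set[int]]:
        """Connected components as sets of vertex ids (BFS over the edge set)."""
        adj: dict[int, set[int]] = {v.id: set() for v in self.vertices}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        seen: set[int] = set()
        comps: list[set[int]] = []
        for start in sorted(adj):
            if start in seen:
                continue
            comp = {start}
            queue = [start]
            while queue:
                node = queue.pop()
                for nb in adj[node]:
                    if nb not in comp:
                        comp.add(nb)
                        queue.append(nb)
            seen |= comp
            comps.append(comp)
        return comps

    def to_networkx(self):
        """Export as a :class:`networkx.Graph` with vertex/edge attributes."""
        import networkx as nx

        g = nx.Graph()
        for v in self.vertices:
            g.add_node(
                v.id,
                interval=v.interval_index,
                members=sorted(v.members),
                attr_mean=v.attr_mean,
            )
        for (u, w), grad in self.edges.items():
            g.add_edge(u, w, gradient=grad)
        return g


@dataclass(frozen=True)
class ClustererSpec:
    """Pluggable per-preimage clustering configuration.

    ``agglomerative`` wraps Ward/complete/average/single linkage with a fixed
    cluster count; ``density`` wraps HDBSCAN with its defaults, in which case
    points labelled as noise are dropped from the graph (standard
    density-clustering semantics).
    """

    method: str = "agglomerative"
    n_clusters: int = 6
    linkage: str = "ward"
    metric: str = "euclidean"
    min_cluster_size: int = 5
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in ("agglomerative", "density"):
            raise ValueError(f"unknown clustering method {self.method!r}")
        if self.method == "agglomerative" and self.n_clusters < 1:
            raise ValueError("agglomerative cluster count must be >= 1")

    def fit_labels(self, X: np.ndarray) -> np.ndarray:
        """Cluster the rows of ``X``; returns integer labels, -1 for noise."""
        n = X.shape[0]
        if self.method == "agglomerative":
            # a preimage smaller than the requested cluster count yields one
            # (singleton-capable) cluster per point rather than an error
            k = min(n, self.n_clusters)
            if n == 1 or k == 1:
                return np.zeros(n, dtype=int)
            metric = self.metric
            if self.linkage == "ward":
                metric = "euclidean"
            model = AgglomerativeClustering(
                n_clusters=k, linkage=self.linkage, metric=metric, **self.params
            )
            return model.fit_predict(X)
        # density: HDBSCAN needs at least min_cluster_size points to form
        # any cluster; smaller preimages are all noise
        if n < max(2, self.min_cluster_size):
            return np.full(n, -1, dtype=int)
        # allow_single_cluster: a preimage frequently IS one cluster, which
        # stock HDBSCAN would otherwise discard wholesale as noise
        params = {"allow_single_cluster": True, "copy": True, **self.params}
        model = HDBSCAN(
            min_cluster_size=self.min_cluster_size, metric=self.metric, **params
        )
        return model.fit_predict(X)


def pullback_cluster(
    data: DataMatrix,
    lens_values: Sequence[float] | np.ndarray,
    cover: Iterable[Interval],
    clusterer: ClustererSpec,
) -> list[MapperVertex]:
    """Cluster each interval's preimage in the original feature space.

    Each cluster becomes one vertex tagged with its source interval; empty
    preimages contribute nothing; density-clustering noise points are
    dropped.  Vertex ids follow (interval_index, cluster label) order so
    repeated runs number vertices identically.
    """
    lens_values = np.asarray(lens_values, dtype=float)
    if lens_values.shape != (data.n_samples,):
        raise ValueError(
            f"lens_values has shape {lens_values.shape}, expected ({data.n_samples},)"
        )
    vertices: list[MapperVertex] = []
    next_id = 0
    for interval in cover:
        idx = np.flatnonzero(interval.contains(lens_values))
        if idx.size == 0:
            continue
        labels = clusterer.fit_labels(data.values[idx])
        for label in sorted(set(labels) - {-1}):
            members = frozenset(int(i) for i in idx[labels == label])
            vertices.append(
                MapperVertex(id=next_id, members=members, interval_index=interval.index)
            )
            next_id += 1
    return vertices


def build_nerve(vertices: list[MapperVertex]) -> MapperGraph:
    """Join every pair of distinct vertices sharing at least one sample.

    All vertex pairs are compared (with a sample-to-vertex inverted index as
    a prefilter): at high overlap fractions non-adjacent intervals intersect,
    so restricting to neighbouring intervals would miss edges.
    """
    by_sample: dict[int, list[int]] = {}
    for v in vertices:
        for m in v.members:
            by_sample.setdefault(m, []).append(v.id)
    edges: dict[tuple[int, int], float | None] = {}
    for owners in by_sample.values():
        if len(owners) < 2:
            continue
        owners = sorted(owners)
        for i, u in enumerate(owners):
            for w in owners[i + 1 :]:
                edges[(u, w)] = None
    return MapperGraph(vertices=list(vertices), edges=edges)


def build_mapper(
    data: DataMatrix,
    lens_values: Sequence[float] | np.ndarray,
    t: int,
    p: float,
    clusterer: ClustererSpec,
) -> MapperGraph:
    """Full Mapper construction: cover the observed lens range, cluster each
    preimage, and return the nerve graph."""
    lens_values = np.asarray(lens_values, dtype=float)
    cover = build_cover((float(lens_values.min()), float(lens_values.max())), t, p)
    vertices = pullback_cluster(data, lens_values, cover, clusterer)
    return build_nerve(vertices)
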