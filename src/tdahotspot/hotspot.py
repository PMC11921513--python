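"""Hotspot detection on an annotated Mapper graph.

A hotspot is a small, connected, internally homogeneous community of Mapper
vertices whose attribute mean differs sharply from its graph neighbourhood.
Detection proceeds in two stages:

1. *Community detection* — vertices are annotated with the mean attribute
   Â(v) of their member samples; every edge receives the gradient weight
   F'(u,v) = |Â(u) - Â(v)|; single-linkage clustering of vertices under F'
   (restricted to graph edges; non-edges are at infinite distance) is cut at
   the largest gap between consecutive distinct merge heights, yielding
   attribute-homogeneous communities.
2. *Community classification* — a community is a hotspot when its unique
   sample count S is at least sigma1, its neighbourhood (all other vertices)
   is larger by more than sigma2 = MAD of all community sizes, and the
   attribute gap to the neighbourhood exceeds epsilon in the requested
   direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .mapper import MapperGraph

__all__ = [
    "AttributeVector",
    "Dendrogram",
    "Community",
    "HotspotConfig",
    "ClassificationRecord",
    "RejectionReason",
    "annotate_attribute",
    "annotate_gradient",
    "single_linkage_on_graph",
    "cut_dendrogram",
    "classify_communities",
    "mad",
    "detect_hotspots",
]


def as_attribute(values: Sequence[float] | np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("attribute must be a 1-D vector")
    if not np.all(np.isfinite(arr)):
        raise ValueError("attribute contains missing/non-finite values")
    return arr


#: alias used in signatures; one real value A(x) per sample
AttributeVector = np.ndarray


@dataclass(frozen=True)
class Merge:
    height: float
    groups: tuple[frozenset[int], frozenset[int]]


@dataclass(frozen=True)
class Dendrogram:
    """Ordered single-linkage merge sequence; heights are nondecreasing."""

    merges: tuple[Merge, ...]

    def heights(self) -> np.ndarray:
        return np.array([m.height for m in self.merges])


@dataclass(frozen=True)
class Community:
    """A connected, attribute-homogeneous group of Mapper vertices."""

    vertex_ids: frozenset[int]
    sample_ids: frozenset[int]
    attr_mean: float

    @property
    def size(self) -> int:
        """Unique-sample size S (Mapper overlap duplicates samples across
        vertices; patients are counted once)."""
        return len(self.sample_ids)


class RejectionReason(str, Enum):
    NONE = "none"
    TOO_SMALL = "too_small"
    NOT_PROPORTIONALLY_SMALL = "not_proportionally_small"
    GAP_BELOW_EPSILON = "gap_below_epsilon"
    DEGENERATE = "degenerate"


@dataclass(frozen=True)
class HotspotConfig:
    """User-set thresholds: minimum hotspot size sigma1, minimum attribute
    gap epsilon, and the direction of the sought anomaly."""

    sigma1: int = 30
    epsilon: float = 0.1
    direction: str = "high"

    def __post_init__(self) -> None:
        if self.sigma1 < 1:
            raise ValueError("sigma1 must be >= 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.direction not in ("high", "low", "both"):
            raise ValueError(f"direction must be high/low/both, got {self.direction!r}")


@dataclass(frozen=True)
class ClassificationRecord:
    community: Community
    neighbourhood_size: int
    neighbourhood_attr_mean: float
    sigma2: float
    is_hotspot: bool
    rejection_reason: RejectionReason

    def __post_init__(self) -> None:
        if self.is_hotspot and self.rejection_reason is not RejectionReason.NONE:
            raise ValueError("a hotspot cannot carry a rejection reason")


def annotate_attribute(graph: MapperGraph, attr: np.ndarray) -> MapperGraph:
    """Set each vertex's Â to the arithmetic mean of A over its members."""
    attr = as_attribute(attr)
    for v in graph.vertices:
        members = sorted(v.members)
        if members[-1] >= attr.size or members[0] < 0:
            raise IndexError(
                f"vertex {v.id} references sample {members[-1]} outside the "
                f"attribute vector of length {attr.size}"
            )
        v.attr_mean = float(attr[members].mean())
    return graph


def annotate_gradient(graph: MapperGraph) -> MapperGraph:
    """Set every edge weight to F' = |Â(u) - Â(v)|."""
    by_id = graph._by_id
    for u, w in list(graph.edges):
        au, aw = by_id[u].attr_mean, by_id[w].attr_mean
        if au is None or aw is None:
            raise ValueError("attribute means must be annotated before gradients")
        graph.edges[(u, w)] = abs(au - aw)
    return graph


def single_linkage_on_graph(graph: MapperGraph) -> Dendrogram:
    """Graph-restricted single linkage of vertices under the gradient F'.

    Equivalent to Kruskal's minimum-spanning-forest construction: edges are
    processed in nondecreasing F' order and a merge is recorded whenever an
    edge unites two distinct vertex groups, at height equal to that edge's
    weight.  Vertices in different connected components of the graph are at
    infinite distance and never merge.
    """
    parent = {v.id: v.id for v in graph.vertices}
    groups = {v.id: frozenset([v.id]) for v in graph.vertices}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # deterministic tie-break: weight, then vertex-id order
    order = sorted(graph.edges.items(), key=lambda kv: (kv[1], kv[0]))
    merges: list[Merge] = []
    for (u, w), weight in order:
        if weight is None:
            raise ValueError("gradients must be annotated before single linkage")
        ru, rw = find(u), find(w)
        if ru == rw:
            continue
        merges.append(Merge(height=float(weight), groups=(groups[ru], groups[rw])))
        parent[rw] = ru
        groups[ru] = groups[ru] | groups[rw]
    return Dendrogram(merges=tuple(merges))


def _cut_threshold(heights: np.ndarray) -> float | None:
    """Midpoint of the largest gap between consecutive distinct merge
    heights; ties resolve to the lowest gap (most conservative cut).
    Returns None when there is no gap to cut (fewer than two distinct
    heights, or all gaps zero)."""
    H = np.unique(heights)
    if H.size <= 1:
        return None
    gaps = np.diff(H)
    best = int(np.argmax(gaps))  # argmax returns the first (lowest) maximum
    if gaps[best] <= 0:
        return None
    return float((H[best] + H[best + 1]) / 2.0)


def _components_to_communities(
    kept: MapperGraph, by_id: dict[int, MapperVertex]
) -> list[Community]:
    communities = []
    for comp in kept.connected_components():
        samples: set[int] = set()
        means = []
        for vid in comp:
            samples |= by_id[vid].members
            means.append(by_id[vid].attr_mean)
        communities.append(
            Community(
                vertex_ids=frozenset(comp),
                sample_ids=frozenset(samples),
                attr_mean=float(np.mean(means)),
            )
        )
    return communities


def cut_dendrogram(
    dendrogram: Dendrogram,
    graph: MapperGraph,
    per_component: bool = False,
) -> list[Community]:
    """Cut the merge sequence at the largest height gap and return the
    resulting communities (connected components under edges with F' < tau).

    By default the gap is found on the pooled merge heights of the whole
    forest; with ``per_component`` each connected component of the graph is
    cut at the largest gap of its own merge heights.  When no gap exists,
    each connected component is one community.  Communities always
    partition the vertex set.
    """
    by_id = graph._by_id
    if per_component and dendrogram.merges:
        communities = []
        for comp in graph.connected_components():
            heights = np.array(
                [m.height for m in dendrogram.merges if m.groups[0] <= comp]
            )
            tau = _cut_threshold(heights) if heights.size else None
            comp_edges = {
                e: w
                for e, w in graph.edges.items()
                if e[0] in comp and (tau is None or (w is not None and w < tau))
            }
            sub = MapperGraph(vertices=[by_id[v] for v in comp], edges=comp_edges)
            communities.extend(_components_to_communities(sub, by_id))
        communities.sort(key=lambda c: min(c.vertex_ids))
        return communities
    tau = _cut_threshold(dendrogram.heights()) if dendrogram.merges else None
    if tau is None:
        kept = MapperGraph(vertices=graph.vertices, edges=dict(graph.edges))
    else:
        kept_edges = {e: w for e, w in graph.edges.items() if w is not None and w < tau}
        kept = MapperGraph(vertices=graph.vertices, edges=kept_edges)
    communities = _components_to_communities(kept, by_id)
    # deterministic order: by smallest vertex id
    communities.sort(key=lambda c: min(c.vertex_ids))
    return communities


def mad(values: Sequence[float] | np.ndarray) -> float:
    """Unnormalised median absolute deviation: median(|v - median(v)|)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("mad of an empty vector is undefined")
    return float(np.median(np.abs(arr - np.median(arr))))


def classify_communities(
    communities: Sequence[Community],
    graph: MapperGraph,
    config: HotspotConfig,
    weighted_neighbourhood: bool = False,
) -> list[ClassificationRecord]:
    """Apply the size, proportionality and attribute-gap tests to each
    community.

    The neighbourhood of a community is every other vertex in the graph;
    its attribute mean is the unweighted mean of Â over those vertices
    (or, with ``weighted_neighbourhood``, the mean weighted by vertex
    member counts) and its size the count of their unique samples.  sigma2
    is the MAD of all community sizes.  With fewer than two communities
    there is no neighbourhood to compare against and every record is
    rejected as degenerate.
    """
    if not communities:
        raise ValueError("classification requires at least one community")
    by_id = graph._by_id
    sizes = [c.size for c in communities]
    sigma2 = mad(sizes)
    records: list[ClassificationRecord] = []
    for comm in communities:
        other_vids = [v.id for v in graph.vertices if v.id not in comm.vertex_ids]
        nbr_samples: set[int] = set()
        for vid in other_vids:
            nbr_samples |= by_id[vid].members
        nbr_size = len(nbr_samples)
        if not other_vids:
            nbr_mean = float("nan")
        elif weighted_neighbourhood:
            weights = np.array([len(by_id[vid].members) for vid in other_vids])
            means = np.array([by_id[vid].attr_mean for vid in other_vids])
            nbr_mean = float(np.average(means, weights=weights))
        else:
            nbr_mean = float(np.mean([by_id[vid].attr_mean for vid in other_vids]))
        if len(communities) < 2:
            reason = RejectionReason.DEGENERATE
        elif comm.size < config.sigma1:
            reason = RejectionReason.TOO_SMALL
        elif nbr_size - comm.size < sigma2:
            reason = RejectionReason.NOT_PROPORTIONALLY_SMALL
        else:
            gap = comm.attr_mean - nbr_mean
            if config.direction == "high":
                ok = gap > config.epsilon
            elif config.direction == "low":
                ok = -gap > config.epsilon
            else:
                ok = abs(gap) > config.epsilon
            reason = RejectionReason.NONE if ok else RejectionReason.GAP_BELOW_EPSILON
        records.append(
            ClassificationRecord(
                community=comm,
                neighbourhood_size=nbr_size,
                neighbourhood_attr_mean=nbr_mean,
                sigma2=sigma2,
                is_hotspot=reason is RejectionReason.NONE,
                rejection_reason=reason,
            )
        )
    return records


def detect_hotspots(
    graph: MapperGraph,
    attr: np.ndarray,
    config: HotspotConfig,
    per_component: bool = False,
    weighted_neighbourhood: bool = False,
) -> list[ClassificationRecord]:
    """Full pipeline: annotate Â and F', single-linkage community detection
    with the largest-gap cut, then classify every community."""
    if graph.n_vertices == 0:
        return []
    annotate_attribute(graph, attr)
    annotate_gradient(graph)
    dendrogram = single_linkage_on_graph(graph)
    communities = cut_dendrogram(dendrogram, graph, per_component=per_component)
    return classify_communities(
        communities, graph, config, weighted_neighbourhood=weighted_neighbourhood
    )
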