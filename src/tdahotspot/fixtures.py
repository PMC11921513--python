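"""Synthetic datasets with planted hotspots.

Two generators make every stage of the pipeline testable without external
data:

* :func:`generate_two_circles` — 5000 points on two concentric circles with
  a contiguous arc of the outer ring labelled Class 1 (8.1%, n = 405 by
  default); the classic demonstration that a Mapper graph separates the two
  rings and that the arc forms a detectable attribute hotspot.
* :func:`generate_survival_fixture` — well-separated Gaussian clusters in
  feature space where one designated small cluster carries a multiplied
  event hazard, emulating the statistical structure of a cohort containing
  a small poor-prognosis subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hotspot import AttributeVector
from .mapper import DataMatrix
from .stats import SurvivalData, event_before_horizon

__all__ = [
    "TwoCirclesSpec",
    "SurvivalFixtureSpec",
    "generate_two_circles",
    "generate_survival_fixture",
]


@dataclass(frozen=True)
class TwoCirclesSpec:
    """Two concentric rings with a planted Class-1 arc on the outer ring.

    Radii, radial noise and arc placement are free choices of the fixture
    (the statistical contract is the class fraction and the ring geometry):
    outer radius 1.0, inner radius 0.5, radial Gaussian noise 0.03, arc
    centred at 45 degrees, samples split evenly between the rings.
    """

    n_total: int = 5000
    class1_frac: float = 0.081
    outer_radius: float = 1.0
    inner_radius: float = 0.5
    noise_sd: float = 0.03
    arc_center_deg: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.class1_frac < 1.0):
            raise ValueError("class1_frac must lie in (0, 1)")
        if self.inner_radius >= self.outer_radius:
            raise ValueError("inner_radius must be smaller than outer_radius")
        if self.n_total < 2:
            raise ValueError("n_total must be >= 2")


def generate_two_circles(
    spec: TwoCirclesSpec,
) -> tuple[DataMatrix, AttributeVector, frozenset[str]]:
    """Sample the two-circles dataset; returns (matrix, attribute, truth ids).

    Points are uniform in angle on each ring with radial Gaussian noise.
    Class 1 is the ``round(class1_frac * n_total)`` outer-ring points whose
    angles are closest (circularly) to the arc centre — assignment by
    angular order keeps the planted count exact.  The attribute is the
    Class-1 indicator.
    """
    rng = np.random.default_rng(spec.seed)
    n_outer = spec.n_total // 2 + spec.n_total % 2
    n_inner = spec.n_total - n_outer
    n_class1 = int(round(spec.class1_frac * spec.n_total))
    if n_class1 > n_outer:
        raise ValueError(
            f"class1 count {n_class1} exceeds outer-ring count {n_outer}"
        )

    def ring(n: int, radius: float) -> tuple[np.ndarray, np.ndarray]:
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
        r = radius + rng.normal(0.0, spec.noise_sd, size=n)
        return np.column_stack([r * np.cos(theta), r * np.sin(theta)]), theta

    outer_xy, outer_theta = ring(n_outer, spec.outer_radius)
    inner_xy, _ = ring(n_inner, spec.inner_radius)

    center = np.deg2rad(spec.arc_center_deg)
    circ_dist = np.abs((outer_theta - center + np.pi) % (2.0 * np.pi) - np.pi)
    arc_local = np.argsort(circ_dist, kind="stable")[:n_class1]

    values = np.vstack([outer_xy, inner_xy])
    attr = np.zeros(spec.n_total)
    attr[arc_local] = 1.0
    ids = tuple(f"s{i:04d}" for i in range(spec.n_total))
    truth = frozenset(ids[i] for i in arc_local)
    return DataMatrix(values=values, sample_ids=ids), attr, truth


@dataclass(frozen=True)
class SurvivalFixtureSpec:
    """Gaussian clusters with one designated small high-hazard cluster.

    The first cluster in ``cluster_sizes`` is the planted hotspot and must
    be strictly the smallest.  Event times are exponential with the baseline
    hazard, multiplied by ``hotspot_hazard_ratio`` in the designated
    cluster; censoring is an independent exponential.  Defaults give a
    background 10-year event probability near 35% (hazard -ln(0.65)/120 per
    month) so the neighbourhood survival resembles an ER+ relapse cohort.
    """

    cluster_sizes: tuple[int, ...] = (40, 700, 700)
    n_features: int = 10
    separation: float = 6.0
    baseline_hazard: float = 0.00359
    hotspot_hazard_ratio: float = 6.0
    censor_rate: float = 0.002
    horizon: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.cluster_sizes)
        if len(sizes) < 2 or any(s < 1 for s in sizes):
            raise ValueError("need >= 2 clusters of positive size")
        if sizes[0] >= min(sizes[1:]):
            raise ValueError("the designated (first) cluster must be the smallest")
        if self.n_features < len(sizes):
            raise ValueError("need at least one feature per cluster for the centers")
        if self.baseline_hazard <= 0 or self.hotspot_hazard_ratio <= 0:
            raise ValueError("hazards must be positive")
        if self.censor_rate < 0 or self.horizon <= 0:
            raise ValueError("invalid censor_rate/horizon")
        object.__setattr__(self, "cluster_sizes", sizes)

    @property
    def n_total(self) -> int:
        return sum(self.cluster_sizes)


def generate_survival_fixture(
    spec: SurvivalFixtureSpec,
) -> tuple[DataMatrix, AttributeVector, SurvivalData, frozenset[str]]:
    """Sample the survival fixture; returns (matrix, attribute, survival,
    truth ids).

    Cluster centres sit on scaled coordinate axes (``separation`` apart from
    the origin) with unit isotropic noise, so agglomerative clustering
    separates them cleanly.  The attribute is the event-before-horizon
    indicator derived from the censored follow-up.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.cluster_sizes)
    centers = np.zeros((k, spec.n_features))
    for i in range(k):
        centers[i, i] = spec.separation

    rows = []
    hazards = []
    cluster_of = []
    for ci, size in enumerate(spec.cluster_sizes):
        rows.append(centers[ci] + rng.normal(size=(size, spec.n_features)))
        rate = spec.baseline_hazard * (spec.hotspot_hazard_ratio if ci == 0 else 1.0)
        hazards.append(np.full(size, rate))
        cluster_of.extend([ci] * size)
    values = np.vstack(rows)
    hazard = np.concatenate(hazards)

    event_time = rng.exponential(1.0 / hazard)
    if spec.censor_rate > 0:
        censor_time = rng.exponential(1.0 / spec.censor_rate, size=spec.n_total)
    else:
        censor_time = np.full(spec.n_total, np.inf)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    survival = SurvivalData(time, event)
    attr = event_before_horizon(survival, spec.horizon)

    ids = tuple(f"s{i:04d}" for i in range(spec.n_total))
    truth = frozenset(
        ids[i] for i in range(spec.n_total) if cluster_of[i] == 0
    )
    return DataMatrix(values=values, sample_ids=ids), attr, survival, truth
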