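"""Statistics for ranking and validating hotspots.

Log-rank comparison and Kaplan-Meier estimation are delegated to lifelines;
Canberra distances go through scipy.  The survival horizon used throughout
is 10-year relapse-free survival (120 months): records are administratively
censored at the horizon before testing, and the binary attribute fed to
hotspot detection is "event observed before the horizon".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.spatial.distance import canberra as _scipy_canberra

from .mapper import DataMatrix

__all__ = [
    "SurvivalRecord",
    "SurvivalData",
    "GroupComparison",
    "DEFAULT_HORIZON_MONTHS",
    "censor_at_horizon",
    "event_before_horizon",
    "logrank_test",
    "km_survival_at",
    "canberra_distance",
    "centroid_similarity",
    "confusion_f1",
]

DEFAULT_HORIZON_MONTHS = 120.0


@dataclass(frozen=True)
class SurvivalRecord:
    """Per-sample follow-up: time in months and the event indicator."""

    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("follow-up time must be nonnegative")


class SurvivalData:
    """Column-wise container for a cohort's survival records."""

    def __init__(self, times: Sequence[float], events: Sequence[bool]) -> None:
        self.times = np.asarray(times, dtype=float)
        self.events = np.asarray(events, dtype=bool)
        if self.times.shape != self.events.shape or self.times.ndim != 1:
            raise ValueError("times and events must be 1-D and equal length")
        if np.any(self.times < 0):
            raise ValueError("follow-up times must be nonnegative")

    def __len__(self) -> int:
        return self.times.size

    def subset(self, idx: Sequence[int]) -> "SurvivalData":
        idx = np.asarray(list(idx), dtype=int)
        return SurvivalData(self.times[idx], self.events[idx])

    def records(self) -> list[SurvivalRecord]:
        return [SurvivalRecord(float(t), bool(e)) for t, e in zip(self.times, self.events)]


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    degenerate: bool = False  # no events in either group; p fixed at 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def _as_survival(group: SurvivalData | Sequence[SurvivalRecord]) -> SurvivalData:
    if isinstance(group, SurvivalData):
        return group
    return SurvivalData([r.time for r in group], [r.event for r in group])


def censor_at_horizon(
    data: SurvivalData, horizon: float = DEFAULT_HORIZON_MONTHS
) -> SurvivalData:
    """Administratively censor every record at the horizon: times are capped
    and events past the horizon are treated as censored."""
    times = np.minimum(data.times, horizon)
    events = data.events & (data.times <= horizon)
    return SurvivalData(times, events)


def event_before_horizon(
    data: SurvivalData, horizon: float = DEFAULT_HORIZON_MONTHS
) -> np.ndarray:
    """Binary attribute: 1 if the event was observed strictly before the
    horizon, else 0."""
    return (data.events & (data.times < horizon)).astype(float)


def logrank_test(
    group_a: SurvivalData | Sequence[SurvivalRecord],
    group_b: SurvivalData | Sequence[SurvivalRecord],
) -> GroupComparison:
    """Two-group log-rank test (unstratified, 1 df).

    With zero events in both groups the statistic is undefined; the
    comparison is returned with p = 1 and the ``degenerate`` flag set.
    """
    a, b = _as_survival(group_a), _as_survival(group_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    if not (a.events.any() or b.events.any()):
        return GroupComparison(0.0, 1.0, len(a), len(b), degenerate=True)
    result = _ll_logrank(a.times, b.times, event_observed_A=a.events, event_observed_B=b.events)
    return GroupComparison(
        statistic=float(result.test_statistic),
        p_value=float(min(result.p_value, 1.0)),
        n_a=len(a),
        n_b=len(b),
    )


def km_survival_at(
    records: SurvivalData | Sequence[SurvivalRecord], horizon: float
) -> float:
    """Kaplan-Meier product-limit estimate S(horizon) = Π (1 - d_i/n_i)."""
    data = _as_survival(records)
    if len(data) == 0:
        raise ValueError("records must be nonempty")
    if horizon < 0:
        raise ValueError("horizon must be nonnegative")
    kmf = KaplanMeierFitter()
    kmf.fit(data.times, event_observed=data.events)
    return float(kmf.predict(horizon))


def km_curve(records: SurvivalData | Sequence[SurvivalRecord]):
    """KM curve as arrays (time, at_risk, survival) for export/plotting."""
    data = _as_survival(records)
    kmf = KaplanMeierFitter()
    kmf.fit(data.times, event_observed=data.events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    return (
        np.asarray(table.index, dtype=float),
        np.asarray(table["at_risk"], dtype=int),
        np.asarray(surv.reindex(table.index), dtype=float),
    )


def canberra_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """Canberra distance Σ |x_i - y_i| / (|x_i| + |y_i|); coordinates where
    both values are exactly zero contribute nothing.  Sensitive to values
    near zero, which suits z-score-like expression deviations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return float(_scipy_canberra(x, y))


def centroid_similarity(
    data: DataMatrix,
    reference_centroid: Sequence[float],
    feature_subset: Sequence[int],
) -> np.ndarray:
    """Per-sample Canberra distance to a reference centroid, restricted to a
    feature subset (typically the lens's nonzero genes).

    The reference centroid of a discovery hotspot is the feature-wise mean
    over its samples; scoring a validation cohort against it colours the
    validation graph by similarity to the discovered subgroup.
    """
    subset = np.asarray(sorted(set(int(i) for i in feature_subset)), dtype=int)
    if subset.size == 0:
        raise ValueError("feature_subset must be nonempty")
    if subset.min() < 0 or subset.max() >= data.n_features:
        raise ValueError("feature_subset index out of range")
    centroid = np.asarray(reference_centroid, dtype=float)
    if centroid.shape == (data.n_features,):
        centroid = centroid[subset]
    if centroid.shape != (subset.size,):
        raise ValueError(
            f"centroid has shape {centroid.shape}, expected ({subset.size},)"
        )
    restricted = data.values[:, subset]
    return np.array([canberra_distance(row, centroid) for row in restricted])


def confusion_f1(
    predicted: set, truth: set, universe: int
) -> dict[str, float | int | None]:
    """Binary confusion counts and precision/recall/F1 of a predicted sample
    set against a ground-truth set drawn from ``universe`` samples."""
    predicted, truth = set(predicted), set(truth)
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = universe - tp - fp - fn
    if tn < 0:
        raise ValueError("universe smaller than the union of predicted and truth")
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    if precision and recall:
        f1 = 2 * precision * recall / (precision + recall)
    elif precision is None or recall is None:
        f1 = None
    else:
        f1 = 0.0
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }
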