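"""Random sparse linear lens functions.

A lens is a linear projection f(x) = Σ α_i x_i whose coefficient vector is
sparse: the number of nonzero coefficients is drawn uniformly from
[1, floor(max_nonzero_frac · n)], their positions are a uniform subset of the
features, and their values are uniform on [coeff_lo, coeff_hi] (default
[-2.5, 2.5]).  Sampling doubles as feature selection: each candidate lens
examines the data through a different random gene subset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

from .mapper import DataMatrix

__all__ = [
    "LensFunction",
    "sample_lens",
    "apply_lens",
    "lens_stream",
    "save_lens",
    "load_lens",
]

DEFAULT_COEFF_LO = -2.5
DEFAULT_COEFF_HI = 2.5
DEFAULT_MAX_NONZERO_FRAC = 0.5


@dataclass(frozen=True)
class LensFunction:
    """A sparse linear projection of feature space onto the real line."""

    coefficients: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        coeff = np.asarray(self.coefficients, dtype=float)
        if coeff.ndim != 1:
            raise ValueError("coefficients must be a 1-D vector")
        object.__setattr__(self, "coefficients", coeff)

    @property
    def n_features(self) -> int:
        return self.coefficients.size

    @property
    def nonzero_indices(self) -> frozenset[int]:
        return frozenset(int(i) for i in np.flatnonzero(self.coefficients))


def sample_lens(
    n_features: int,
    max_nonzero_frac: float = DEFAULT_MAX_NONZERO_FRAC,
    coeff_lo: float = DEFAULT_COEFF_LO,
    coeff_hi: float = DEFAULT_COEFF_HI,
    rng_seed: int = 0,
    feature_subset: frozenset[int] | None = None,
) -> LensFunction:
    """Draw one sparse random linear lens.

    Parameters
    ----------
    n_features
        Dimension of the data the lens will be applied to.
    max_nonzero_frac
        Upper bound on the fraction of nonzero coefficients; the nonzero
        count is uniform on ``[1, max(1, floor(max_nonzero_frac*n))]``.
    coeff_lo, coeff_hi
        Range of the uniform distribution for nonzero coefficients.
    rng_seed
        Seed; the draw is fully reproducible from it.
    feature_subset
        Optional pre-selection of informative features: nonzero positions
        are drawn only from this set.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if not (0.0 < max_nonzero_frac <= 1.0):
        raise ValueError(f"max_nonzero_frac must be in (0, 1], got {max_nonzero_frac}")
    if coeff_lo >= coeff_hi:
        raise ValueError("coeff_lo must be < coeff_hi")
    pool = (
        np.arange(n_features)
        if feature_subset is None
        else np.array(sorted(feature_subset), dtype=int)
    )
    if pool.size == 0 or pool.min() < 0 or pool.max() >= n_features:
        raise ValueError("feature_subset must be a nonempty subset of feature indices")
    rng = np.random.default_rng(rng_seed)
    max_nonzero = max(1, int(np.floor(max_nonzero_frac * pool.size)))
    n_nonzero = int(rng.integers(1, max_nonzero + 1))
    positions = rng.choice(pool, size=n_nonzero, replace=False)
    coeff = np.zeros(n_features)
    coeff[positions] = rng.uniform(coeff_lo, coeff_hi, size=n_nonzero)
    return LensFunction(coefficients=coeff, seed=int(rng_seed))


def apply_lens(data: DataMatrix, lens: LensFunction) -> np.ndarray:
    """Evaluate f(x) = Σ α_i x_i for every sample; returns one value per row."""
    if lens.n_features != data.n_features:
        raise ValueError(
            f"lens has {lens.n_features} coefficients for {data.n_features} features"
        )
    return data.values @ lens.coefficients


def _derive_seed(master_seed: int, index: int) -> int:
    """Stable, injective-in-practice child seed below 2**31."""
    state = np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)
    return int(state[0] % (2**31))


def lens_stream(
    n_features: int,
    master_seed: int,
    max_nonzero_frac: float = DEFAULT_MAX_NONZERO_FRAC,
    coeff_lo: float = DEFAULT_COEFF_LO,
    coeff_hi: float = DEFAULT_COEFF_HI,
    feature_subset: frozenset[int] | None = None,
) -> Iterator[LensFunction]:
    """Infinite reproducible stream of candidate lenses for the search loop."""
    index = 0
    while True:
        yield sample_lens(
            n_features,
            max_nonzero_frac=max_nonzero_frac,
            coeff_lo=coeff_lo,
            coeff_hi=coeff_hi,
            rng_seed=_derive_seed(master_seed, index),
            feature_subset=feature_subset,
        )
        index += 1


def save_lens(lens: LensFunction, path: str | Path) -> None:
    """Serialise a lens as JSON (sparse index->value map) so a discovery lens
    can be re-applied verbatim to a validation dataset."""
    payload = {
        "seed": lens.seed,
        "n_features": lens.n_features,
        "coefficients": {
            str(i): float(lens.coefficients[i]) for i in sorted(lens.nonzero_indices)
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_lens(path: str | Path) -> LensFunction:
    payload = json.loads(Path(path).read_text())
    coeff = np.zeros(int(payload["n_features"]))
    for i, value in payload["coefficients"].items():
        coeff[int(i)] = float(value)
    return LensFunction(coefficients=coeff, seed=int(payload["seed"]))
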