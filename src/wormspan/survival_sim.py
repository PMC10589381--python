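"""Weibull survival curves and the training parameter grid.

Lifespan assays track the fraction of a worm population alive on each day of
the experiment.  The two-parameter Weibull survival function

    S(t) = exp(-(t / b) ** a)

is a standard parametric model for such curves: ``b`` (scale, days) tracks the
mean lifespan of the population and ``a`` (shape, dimensionless) the slope of
the mortality wave — large ``a`` concentrates deaths around ``t = b``, small
``a`` spreads them out.  The simulator samples a grid of ``(n_objects,
mean_life, slope)`` triples, evaluates theoretical curves on the assay-day
axis, jitters them so a model trained on them does not overfit the exact
Weibull family, and quantizes to integer live counts which serve as labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WeibullParams",
    "SurvivalCurve",
    "GridSpec",
    "CountTrajectory",
    "weibull_survival",
    "parameter_grid",
    "perturb_curve",
    "quantize_counts",
]


@dataclass(frozen=True)
class WeibullParams:
    """Shape ``a`` (slope of the mortality curve) and scale ``b`` (mean life, days)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"Weibull parameters must be positive, got a={self.a}, b={self.b}")


@dataclass(frozen=True)
class SurvivalCurve:
    """Per-day fraction of the population alive, for assay days ``t = 1..L``.

    Values lie in ``[0, 1]`` and are non-increasing over days.
    """

    fractions: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", f)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("fractions must be a non-empty 1-D sequence")
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("survival fractions must lie in [0, 1]")
        if np.any(np.diff(f) > 1e-12):
            raise ValueError("survival fractions must be non-increasing")

    def __len__(self) -> int:
        return int(self.fractions.size)


@dataclass(frozen=True)
class GridSpec:
    """Inclusive integer ranges for the simulator parameter grid.

    Defaults cover 10–15 worms per plate, mean life 5–57 days and slope 4–20,
    i.e. 6 x 53 x 17 = 5406 theoretical curves.
    """

    n_objects_range: tuple[int, int] = (10, 15)
    mean_life_range: tuple[int, int] = (5, 57)
    slope_range: tuple[int, int] = (4, 20)

    def __post_init__(self) -> None:
        for name in ("n_objects_range", "mean_life_range", "slope_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is empty: [{lo}, {hi}]")

    @property
    def size(self) -> int:
        return int(np.prod([hi - lo + 1 for lo, hi in (
            self.n_objects_range, self.mean_life_range, self.slope_range)]))


@dataclass(frozen=True)
class CountTrajectory:
    """Integer live counts per day, bounded by the initial population size."""

    counts: np.ndarray
    n_initial: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", c)
        if np.any(c < 0) or np.any(c > self.n_initial):
            raise ValueError("counts must lie in [0, n_initial]")
        if np.any(np.diff(c) > 0):
            raise ValueError("counts must be non-increasing")

    def __len__(self) -> int:
        return int(self.counts.size)


def weibull_survival(t, params: WeibullParams):
    """Fraction of the population alive on day ``t``: ``exp(-(t/b)**a)``.

    ``t`` may be a scalar or an array of non-negative days.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = np.exp(-((t / params.b) ** params.a))
    return float(out) if out.ndim == 0 else out


def theoretical_curve(params: WeibullParams, length: int) -> SurvivalCurve:
    """Evaluate the Weibull survival function on assay days ``1..length``."""
    days = np.arange(1, length + 1, dtype=float)
    return SurvivalCurve(weibull_survival(days, params))


def parameter_grid(spec: GridSpec = GridSpec()) -> list[tuple[int, int, int]]:
    """All ``(n_objects, mean_life, slope)`` triples, lexicographic order.

    The default spec yields 5406 triples.
    """
    ranges = [range(lo, hi + 1) for lo, hi in (
        spec.n_objects_range, spec.mean_life_range, spec.slope_range)]
    return list(itertools.product(*ranges))


def perturb_curve(curve: SurvivalCurve, rng: np.random.Generator,
                  magnitude: float = 0.05) -> SurvivalCurve:
    """Jitter each day's fraction by bounded uniform noise.

    Noise is drawn independently per day from ``U(-magnitude, +magnitude)``,
    the result clamped to ``[0, 1]`` and re-monotonized with a running
    minimum so the output is a valid survival curve.  ``magnitude=0`` is the
    identity.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    f = curve.fractions
    if magnitude == 0:
        return SurvivalCurve(f.copy())
    noisy = f + rng.uniform(-magnitude, magnitude, size=f.shape)
    noisy = np.clip(noisy, 0.0, 1.0)
    return SurvivalCurve(np.minimum.accumulate(noisy))


def quantize_counts(curve: SurvivalCurve, n_initial: int) -> CountTrajectory:
    """Convert fractional survival to integer live counts.

    Rounds half up (``round(5.5) = 6``) and re-monotonizes non-increasing.
    """
    if n_initial < 1:
        raise ValueError("n_initial must be >= 1")
    counts = np.floor(curve.fractions * n_initial + 0.5).astype(int)
    counts = np.minimum.accumulate(np.clip(counts, 0, n_initial))
    return CountTrajectory(counts, n_initial)
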