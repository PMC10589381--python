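"""Survival-curve assembly, monotonic correction, errors, log-rank test.

Counting networks produce per-plate daily live counts; plates of one
condition are pooled by summing counts and initial populations day by day.
Raw automated curves can violate monotonicity, so a two-cycle correction is
applied around the strain's mean life (14 days for wild-type N2, 42 for the
long-lived daf-2 mutant): early days — where occlusions and aggregation
hide live worms — are corrected *upwards* (right-to-left running maximum),
late days — where accumulated dirt causes spurious detections — are
corrected *downwards* (left-to-right running minimum).

Agreement between an automated and a manual curve is summarized by per-day
absolute errors on the percent-alive scale, e(d) = |%manual(d) -
%auto(d)|, their mean (MAE) and standard deviation; statistical equivalence
of two curves is assessed with the standard two-group log-rank test on
per-day death counts (worms alive at the final day are right-censored).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines.statistics import logrank_test as _lifelines_logrank

__all__ = [
    "LifespanCurve",
    "StrainProfile",
    "ErrorReport",
    "N2",
    "DAF2",
    "pool_plates",
    "postprocess_curve",
    "error_report",
    "curve_to_events",
    "logrank_test",
]

FIRST_ASSAY_DAY = 4  # counting starts when worms reach adulthood


@dataclass(frozen=True)
class StrainProfile:
    """Strain name and its mean life in days (the post-processing split)."""

    name: str
    mean_life: int

    def __post_init__(self) -> None:
        if self.mean_life < 1:
            raise ValueError("mean_life must be >= 1")


N2 = StrainProfile("N2", 14)
DAF2 = StrainProfile("daf-2", 42)


@dataclass(frozen=True)
class LifespanCurve:
    """Per-day live counts for one plate or one pooled condition."""

    days: np.ndarray
    counts: np.ndarray
    n_initial: int

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=int)
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "counts", counts)
        if days.shape != counts.shape or days.ndim != 1 or days.size == 0:
            raise ValueError("days and counts must be equal-length 1-D sequences")
        if np.any(np.diff(days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if self.n_initial < 1:
            raise ValueError("n_initial must be >= 1")

    @property
    def percent(self) -> np.ndarray:
        """Percent alive per day: counts * 100 / n_initial."""
        return self.counts * 100.0 / self.n_initial

    @classmethod
    def from_counts(cls, counts, n_initial: int | None = None,
                    first_day: int = FIRST_ASSAY_DAY) -> "LifespanCurve":
        counts = np.asarray(counts, dtype=int)
        days = np.arange(first_day, first_day + counts.size)
        if n_initial is None:
            n_initial = int(counts[0]) if counts[0] > 0 else 1
        return cls(days, counts, n_initial)


def _check_same_days(a: LifespanCurve, b: LifespanCurve) -> None:
    if not np.array_equal(a.days, b.days):
        raise ValueError("curves have mismatched day axes")


def pool_plates(plates: list[LifespanCurve]) -> LifespanCurve:
    """Pool plates of one condition: counts and initial populations summed."""
    if not plates:
        raise ValueError("no plates to pool")
    first = plates[0]
    for p in plates[1:]:
        _check_same_days(first, p)
    counts = np.sum([p.counts for p in plates], axis=0)
    n_initial = int(sum(p.n_initial for p in plates))
    return LifespanCurve(first.days.copy(), counts, n_initial)


def postprocess_curve(curve: LifespanCurve, strain: StrainProfile) -> LifespanCurve:
    """Two-cycle monotonic correction split at the strain's mean life.

    Cycle 1 (days <= mean_life): a day lower than a later day is raised —
    right-to-left running maximum, then clamped to ``n_initial``.  Cycle 2
    (days > mean_life): a day higher than the previous day is lowered —
    left-to-right running minimum, seeded by the last cycle-1 value.  The
    result is globally non-increasing and idempotent under re-application.
    """
    counts = curve.counts.astype(int).copy()
    in_cycle1 = curve.days <= strain.mean_life
    idx1 = np.flatnonzero(in_cycle1)
    idx2 = np.flatnonzero(~in_cycle1)
    if idx1.size:
        counts[idx1] = np.maximum.accumulate(counts[idx1][::-1])[::-1]
        counts[idx1] = np.minimum(counts[idx1], curve.n_initial)
    prev = counts[idx1[-1]] if idx1.size else curve.n_initial
    for i in idx2:
        prev = min(prev, counts[i])
        counts[i] = prev
    return LifespanCurve(curve.days.copy(), counts, curve.n_initial)


@dataclass(frozen=True)
class ErrorReport:
    """Per-day absolute percent errors and their mean/standard deviation."""

    per_day: np.ndarray
    mae: float
    std: float


def error_report(manual: LifespanCurve, automatic: LifespanCurve) -> ErrorReport:
    """Daily |%manual - %automatic| with MAE and population std over days."""
    _check_same_days(manual, automatic)
    e = np.abs(manual.percent - automatic.percent)
    return ErrorReport(per_day=e, mae=float(e.mean()), std=float(e.std()))


def curve_to_events(curve: LifespanCurve) -> tuple[np.ndarray, np.ndarray]:
    """Expand a daily-count curve into per-subject (duration, event) pairs.

    Deaths between consecutive capture days are assigned to the later day;
    worms alive on the final day are right-censored there.  Counts are first
    clipped to be non-increasing (the test is defined on valid survival
    data).
    """
    counts = np.minimum.accumulate(np.minimum(curve.counts, curve.n_initial))
    durations, events = [], []
    prev = curve.n_initial
    for day, count in zip(curve.days, counts):
        deaths = prev - count
        durations.extend([day] * deaths)
        events.extend([1] * deaths)
        prev = count
    if prev > 0:  # survivors at end of study
        durations.extend([int(curve.days[-1])] * prev)
        events.extend([0] * prev)
    return np.asarray(durations, dtype=float), np.asarray(events, dtype=int)


def logrank_test(curve_a: LifespanCurve, curve_b: LifespanCurve
                 ) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p-value from daily counts."""
    dur_a, ev_a = curve_to_events(curve_a)
    dur_b, ev_b = curve_to_events(curve_b)
    if dur_a.size == 0 or dur_b.size == 0:
        raise ValueError("empty risk set: a curve has no subjects")
    if np.array_equal(dur_a, dur_b) and np.array_equal(ev_a, ev_b):
        return 0.0, 1.0  # identical curves carry no evidence of difference
    res = _lifelines_logrank(dur_a, dur_b, event_observed_A=ev_a, event_observed_B=ev_b)
    return float(res.test_statistic), float(res.p_value)
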