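import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormspan.lifespan_eval import (
    DAF2,
    N2,
    LifespanCurve,
    StrainProfile,
    curve_to_events,
    error_report,
    logrank_test,
    pool_plates,
    postprocess_curve,
)


def random_curve(rng, n_days=12, n_initial=12, first_day=4, noisy=True):
    """A daily-count curve; optionally with monotonicity violations as a raw
    automated curve would show."""
    f = np.minimum.accumulate(np.sort(rng.random(n_days))[::-1])
    counts = np.floor(f * n_initial + 0.5).astype(int)
    if noisy:
        counts = np.clip(counts + rng.integers(-2, 3, n_days), 0, n_initial)
    days = np.arange(first_day, first_day + n_days)
    return LifespanCurve(days, counts, n_initial)


def logrank_oracle(curve_a, curve_b):
    """Risk-table log-rank statistic computed from first principles."""
    dur_a, ev_a = curve_to_events(curve_a)
    dur_b, ev_b = curve_to_events(curve_b)
    times = np.unique(np.concatenate([dur_a[ev_a == 1], dur_b[ev_b == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in times:
        n1 = np.sum(dur_a >= t)
        n2 = np.sum(dur_b >= t)
        d1 = np.sum((dur_a == t) & (ev_a == 1))
        d2 = np.sum((dur_b == t) & (ev_b == 1))
        n, d = n1 + n2, d1 + d2
        if n < 2 or d == 0:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestLifespanCurve:
    def test_percent_scale(self):
        c = LifespanCurve(np.array([4]), np.array([8]), 11)
        assert c.percent[0] == pytest.approx(72.7, abs=0.05)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            LifespanCurve(np.array([4, 5]), np.array([5, -1]), 10)

    def test_day_axis_must_increase(self):
        with pytest.raises(ValueError):
            LifespanCurve(np.array([5, 4]), np.array([5, 4]), 10)


class TestPoolPlates:
    def test_single_plate_unchanged(self):
        c = random_curve(np.random.default_rng(0))
        pooled = pool_plates([c])
        np.testing.assert_array_equal(pooled.counts, c.counts)
        assert pooled.n_initial == c.n_initial

    def test_counts_and_initials_sum(self):
        days = np.array([4])
        a = LifespanCurve(days, np.array([11]), 11)
        b = LifespanCurve(days, np.array([13]), 13)
        pooled = pool_plates([a, b])
        assert pooled.counts[0] == 24 and pooled.n_initial == 24
        assert pooled.percent[0] == 100.0

    def test_mismatched_day_axes_rejected(self):
        a = LifespanCurve(np.array([4, 5]), np.array([5, 4]), 10)
        b = LifespanCurve(np.array([5, 6]), np.array([5, 4]), 10)
        with pytest.raises(ValueError):
            pool_plates([a, b])


class TestPostprocess:
    def test_monotone_curve_unchanged(self):
        c = LifespanCurve.from_counts([10, 9, 7, 7, 3, 0], 10)
        out = postprocess_curve(c, N2)
        np.testing.assert_array_equal(out.counts, c.counts)

    def test_cycle1_upward_correction(self):
        c = LifespanCurve(np.array([4, 5, 6]), np.array([10, 12, 11]), 15)
        np.testing.assert_array_equal(postprocess_curve(c, N2).counts, [12, 12, 11])

    def test_cycle2_downward_correction(self):
        c = LifespanCurve(np.array([15, 16]), np.array([5, 7]), 15)
        np.testing.assert_array_equal(postprocess_curve(c, N2).counts, [5, 5])

    def test_cycle1_capped_at_initial_population(self):
        c = LifespanCurve(np.array([4, 5]), np.array([9, 12]), 10)
        np.testing.assert_array_equal(postprocess_curve(c, N2).counts, [10, 10])

    def test_monotone_and_idempotent_on_random_curves(self):
        rng = np.random.default_rng(42)
        for i in range(1000):
            strain = StrainProfile("x", int(rng.integers(5, 20)))
            c = random_curve(rng, n_days=int(rng.integers(3, 25)))
            once = postprocess_curve(c, strain)
            assert np.all(np.diff(once.counts) <= 0), i
            twice = postprocess_curve(once, strain)
            np.testing.assert_array_equal(once.counts, twice.counts)

    def test_boundary_day_capped_by_cycle1(self):
        # first cycle-2 day may not exceed the last cycle-1 day
        c = LifespanCurve(np.array([13, 14, 15]), np.array([6, 5, 9]), 12)
        out = postprocess_curve(c, N2)
        assert out.counts[2] <= out.counts[1]


class TestErrorReport:
    def test_identical_curves_zero_error(self):
        c = random_curve(np.random.default_rng(1))
        r = error_report(c, c)
        assert r.mae == 0.0 and r.std == 0.0 and np.all(r.per_day == 0)

    def test_hand_evaluated_example(self):
        m = LifespanCurve(np.array([4, 5]), np.array([10, 5]), 10)
        a = LifespanCurve(np.array([4, 5]), np.array([9, 6]), 10)
        r = error_report(m, a)
        np.testing.assert_allclose(r.per_day, [10.0, 10.0])
        assert r.mae == 10.0 and r.std == 0.0

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(2)
        a, b = random_curve(rng), random_curve(rng)
        ra, rb = error_report(a, b), error_report(b, a)
        assert ra.mae == rb.mae and ra.std == rb.std

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, max_examples=30)
    def test_mae_equals_brute_force_mean(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_curve(rng), random_curve(rng)
        r = error_report(a, b)
        brute = sum(abs(pa - pb) for pa, pb in zip(a.percent, b.percent)) / len(a.days)
        assert r.mae == pytest.approx(brute, abs=1e-12)


class TestLogrank:
    def test_identical_curves_no_difference(self):
        c = random_curve(np.random.default_rng(3), noisy=False)
        stat, p = logrank_test(c, LifespanCurve(c.days, c.counts, c.n_initial))
        assert stat == 0.0 and p == 1.0

    def test_separated_death_days_match_oracle(self):
        a = LifespanCurve(np.arange(1, 25), np.array([10] * 4 + [0] * 20), 10)
        b = LifespanCurve(np.arange(1, 25), np.array([10] * 19 + [0] * 5), 10)
        stat, p = logrank_test(a, b)
        assert stat == pytest.approx(logrank_oracle(a, b), abs=1e-9)
        assert p < 0.001

    def test_agrees_with_risk_table_oracle_on_random_pairs(self):
        rng = np.random.default_rng(4)
        checked = 0
        for _ in range(100):
            a = random_curve(rng, n_days=15, noisy=False)
            b = random_curve(rng, n_days=15, noisy=False)
            if np.array_equal(a.counts, b.counts):
                continue
            stat, _ = logrank_test(a, b)
            assert stat == pytest.approx(logrank_oracle(a, b), abs=1e-9)
            checked += 1
        assert checked >= 90

    def test_doubling_group_sizes_consistent_with_oracle(self):
        rng = np.random.default_rng(5)
        a, b = random_curve(rng, noisy=False), random_curve(rng, noisy=False)
        a2 = LifespanCurve(a.days, a.counts * 2, a.n_initial * 2)
        b2 = LifespanCurve(b.days, b.counts * 2, b.n_initial * 2)
        stat2, _ = logrank_test(a2, b2)
        assert stat2 == pytest.approx(logrank_oracle(a2, b2), abs=1e-9)

    def test_events_expansion_assigns_deaths_to_later_day(self):
        c = LifespanCurve(np.array([4, 5, 6]), np.array([3, 1, 1]), 4)
        dur, ev = curve_to_events(c)
        # 1 death day 4, 2 deaths day 5, 1 survivor censored day 6
        assert sorted(dur[ev == 1]) == [4, 5, 5]
        assert list(dur[ev == 0]) == [6]


def test_strain_profiles():
    assert N2.mean_life == 14 and DAF2.mean_life == 42
    with pytest.raises(ValueError):
        StrainProfile("x", 0)
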