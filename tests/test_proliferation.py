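import math

import numpy as np
import pytest

from cellcap import (
    DivisionRule,
    ExperimentConfig,
    GrowthLaw,
    UsageError,
    adder_cycle_sum_quadrature,
    cycle_duration,
    exponential_cycle_sum,
    inverse_rate_integral,
    linear_cycle_sum,
    next_newborn,
    proliferation_capacity,
    real_valued_cycle_count,
    sizer_cycle_count,
)

ALPHA = 1.0 / 48.0


def iterated_cycle_sum(rule, law, v0, m):
    """Independent route: iterate the map and sum per-cycle durations."""
    total, v = 0.0, v0
    for _ in range(m):
        total += cycle_duration(rule, law, v)
        v = next_newborn(rule, v)
    return total


class TestProliferationCapacity:
    def test_adder_exponential_at_fixed_point(self, adder_rule, doubling_time):
        law = GrowthLaw.exponential(ALPHA)
        res = proliferation_capacity(adder_rule, law, ExperimentConfig(t_f=72.0, v0=30.0))
        assert res.completed_divisions == 2
        expected_residual = (72.0 - 2.0 * doubling_time) / doubling_time
        assert res.residual_fraction == pytest.approx(expected_residual, rel=1e-12)
        assert res.capacity == pytest.approx(2.0 ** (2.0 + expected_residual), rel=1e-12)

    def test_no_doubling_branch(self, adder_rule, doubling_time):
        # horizon shorter than the first cycle: zero divisions, capacity in [1, 2)
        law = GrowthLaw.exponential(ALPHA)
        res = proliferation_capacity(adder_rule, law, ExperimentConfig(t_f=30.0, v0=30.0))
        assert res.completed_divisions == 0
        assert res.capacity == pytest.approx(2.0 ** (30.0 / doubling_time), rel=1e-12)
        assert 1.0 <= res.capacity < 2.0

    def test_linear_adder_capacity_is_size_invariant(self):
        # each adder cycle adds exactly V̄, so at constant growth rate every
        # founder yields capacity 2^(α·T_f/V̄)
        rule = DivisionRule(a=1.0, vbar=30.0, tmin=0.0)
        law = GrowthLaw.linear(1.0)
        for v0 in (5.0, 30.0, 77.0, 200.0):
            res = proliferation_capacity(rule, law, ExperimentConfig(t_f=72.0, v0=v0))
            assert res.capacity == pytest.approx(2.0**2.4, rel=1e-12)

    def test_capacity_bracketed_by_powers_of_two(self, builtin_laws, rng):
        rule = DivisionRule(a=0.8, vbar=30.0, tmin=10.0)
        for law in builtin_laws.values():
            for v0 in rng.uniform(3.0, 120.0, size=10):
                res = proliferation_capacity(rule, law, ExperimentConfig(t_f=96.0, v0=v0))
                assert 2.0**res.completed_divisions <= res.capacity
                assert res.capacity < 2.0 ** (res.completed_divisions + 1)

    def test_capacity_continuous_and_nondecreasing_in_horizon(self, adder_rule):
        law = GrowthLaw.exponential(ALPHA)
        t_grid = np.linspace(5.0, 150.0, 600)
        caps = [
            proliferation_capacity(adder_rule, law, ExperimentConfig(t_f=t, v0=41.0)).capacity
            for t in t_grid
        ]
        diffs = np.diff(caps)
        assert np.all(diffs > -1e-12)
        # no jumps: a discontinuity at a division boundary would step by ~2^D
        assert np.max(diffs) < 0.25


class TestRealValuedCycleCount:
    def test_two_full_cycles_at_fixed_point(self, doubling_time):
        rule = DivisionRule(a=1.0, vbar=30.0, tmin=0.0)
        law = GrowthLaw.exponential(ALPHA)
        cfg = ExperimentConfig(t_f=2.0 * doubling_time, v0=30.0)
        assert real_valued_cycle_count(rule, law, cfg) == pytest.approx(2.0, rel=1e-12)

    def test_floor_equals_completed_divisions(self, builtin_laws, rng):
        rule = DivisionRule(a=0.9, vbar=30.0, tmin=0.0)
        for law in builtin_laws.values():
            for v0 in rng.uniform(5.0, 90.0, size=10):
                cfg = ExperimentConfig(t_f=150.0, v0=v0)
                m = real_valued_cycle_count(rule, law, cfg)
                res = proliferation_capacity(rule, law, cfg)
                assert math.floor(m) == res.completed_divisions

    def test_rejected_with_cycle_floor(self, adder_rule):
        law = GrowthLaw.exponential(ALPHA)
        with pytest.raises(UsageError):
            real_valued_cycle_count(adder_rule, law, ExperimentConfig(t_f=72.0, v0=30.0))


class TestSizerCycleCount:
    def test_fixed_point_value(self, doubling_time):
        law = GrowthLaw.exponential(ALPHA)
        expected = (72.0 - doubling_time) / doubling_time + 1.0
        assert sizer_cycle_count(law, 30.0, 30.0, 72.0) == pytest.approx(expected, rel=1e-12)

    def test_founder_at_threshold_has_zero_first_cycle(self, doubling_time):
        law = GrowthLaw.exponential(ALPHA)
        assert sizer_cycle_count(law, 30.0, 60.0, 72.0) == pytest.approx(
            72.0 / doubling_time + 1.0, rel=1e-12
        )

    def test_agrees_with_generic_cycle_count(self, builtin_laws):
        # two independent code paths: the a=0 closed form vs the generic
        # solver, valid once the horizon covers at least the first cycle
        rule = DivisionRule(a=0.0, vbar=30.0, tmin=0.0)
        for law in builtin_laws.values():
            tbar = inverse_rate_integral(law, 30.0, 60.0)
            for v0 in (9.0, 30.0, 55.0):
                t_f = inverse_rate_integral(law, v0, 60.0) + 1.7 * tbar
                cfg = ExperimentConfig(t_f=t_f, v0=v0)
                assert sizer_cycle_count(law, 30.0, v0, t_f) == pytest.approx(
                    real_valued_cycle_count(rule, law, cfg), rel=1e-10
                )

    def test_nondecreasing_in_founder_size(self, builtin_laws):
        for law in builtin_laws.values():
            counts = [sizer_cycle_count(law, 30.0, v0, 72.0) for v0 in np.linspace(3, 59, 40)]
            assert np.all(np.diff(counts) >= -1e-12)


class TestClosedFormCycleSums:
    def test_exponential_sum_at_fixed_point(self):
        for m in (0, 1, 4):
            assert exponential_cycle_sum(1.0, 30.0, 30.0, ALPHA, m) == pytest.approx(
                m * math.log(2.0) / ALPHA, abs=1e-9
            )

    def test_exponential_first_sizer_cycle(self):
        v0 = 13.0
        expected = math.log(60.0 / v0) / ALPHA
        assert exponential_cycle_sum(0.0, 30.0, v0, ALPHA, 1) == pytest.approx(expected, rel=1e-12)

    def test_exponential_telescoping(self):
        # 48·ln 2.5 equals the two per-cycle log ratios T(60) + T(45)
        total = exponential_cycle_sum(1.0, 30.0, 60.0, ALPHA, 2)
        assert total == pytest.approx(48.0 * math.log(2.5), rel=1e-12)
        per_cycle = 48.0 * (math.log(90.0 / 60.0) + math.log(75.0 / 45.0))
        assert total == pytest.approx(per_cycle, rel=1e-12)

    def test_exponential_sum_matches_iterated_lineage(self, rng):
        for _ in range(200):
            a = rng.uniform(0.0, 2.0)
            vbar = rng.uniform(5.0, 80.0)
            v0 = rng.uniform(1.0, 2.0 * vbar)  # keep division size above newborn size
            alpha = rng.uniform(0.005, 0.1)
            m = int(rng.integers(0, 8))
            law = GrowthLaw.exponential(alpha)
            rule = DivisionRule(a=a, vbar=vbar, tmin=0.0)
            assert exponential_cycle_sum(a, vbar, v0, alpha, m) == pytest.approx(
                iterated_cycle_sum(rule, law, v0, m), rel=1e-10, abs=1e-10
            )

    def test_linear_adder_sum_is_size_invariant(self):
        for v0 in (4.0, 30.0, 90.0):
            assert linear_cycle_sum(1.0, 30.0, v0, 1.0, 5) == pytest.approx(150.0, rel=1e-12)

    def test_linear_sizer_first_cycle_correction(self):
        # a=0, V0 < V̄: total = mV̄/α + (V̄ − V0)/α
        assert linear_cycle_sum(0.0, 30.0, 12.0, 1.0, 3) == pytest.approx(90.0 + 18.0, rel=1e-12)

    def test_linear_sum_increasing_in_founder_for_a_above_one(self):
        sums = [linear_cycle_sum(1.5, 30.0, v0, 1.0, 4) for v0 in np.linspace(31, 200, 30)]
        assert np.all(np.diff(sums) > 0)

    def test_linear_timer_limit_equals_direct_summation(self):
        rule = DivisionRule(a=2.0, vbar=30.0, tmin=0.0)
        law = GrowthLaw.linear(1.0)
        for v0, m in ((12.0, 4), (45.0, 6)):
            assert linear_cycle_sum(2.0, 30.0, v0, 1.0, m) == pytest.approx(
                iterated_cycle_sum(rule, law, v0, m), rel=1e-12
            )

    def test_linear_sum_matches_iterated_lineage(self, rng):
        for _ in range(200):
            a = rng.uniform(0.0, 1.99)
            vbar = rng.uniform(5.0, 80.0)
            v0 = rng.uniform(1.0, 2.0 * vbar)  # keep division size above newborn size
            alpha = rng.uniform(0.1, 5.0)
            m = int(rng.integers(0, 8))
            rule = DivisionRule(a=a, vbar=vbar, tmin=0.0)
            law = GrowthLaw.linear(alpha)
            assert linear_cycle_sum(a, vbar, v0, alpha, m) == pytest.approx(
                iterated_cycle_sum(rule, law, v0, m), rel=1e-10, abs=1e-10
            )


class TestAdderChangeOfVariables:
    def test_exponential_fixed_point(self):
        assert adder_cycle_sum_quadrature(
            GrowthLaw.exponential(ALPHA), 30.0, 30.0, 3
        ) == pytest.approx(3.0 * math.log(2.0) / ALPHA, rel=1e-9)

    def test_single_cycle_equals_inverse_rate_integral(self):
        law = GrowthLaw.power_saturating(ALPHA, 20.0, 3.0)
        assert adder_cycle_sum_quadrature(law, 30.0, 30.0, 1) == pytest.approx(
            inverse_rate_integral(law, 30.0, 60.0), rel=1e-9
        )

    def test_matches_per_cycle_integrals(self, builtin_laws):
        rule = DivisionRule(a=1.0, vbar=30.0, tmin=0.0)
        for law in builtin_laws.values():
            for v0 in (9.0, 30.0, 70.0):
                assert adder_cycle_sum_quadrature(law, 30.0, v0, 4) == pytest.approx(
                    iterated_cycle_sum(rule, law, v0, 4), rel=1e-9
                )

    def test_decreasing_in_founder_size_for_increasing_law(self):
        law = GrowthLaw.saturating(ALPHA, 25.0)
        sums = [adder_cycle_sum_quadrature(law, 30.0, v0, 3) for v0 in np.linspace(5, 90, 20)]
        assert np.all(np.diff(sums) < 0)
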