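"""Soft-bound STDP rule, device variation sampling and update application."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from memstdp import (
    StdpParams,
    VariationSpec,
    apply_update,
    classical_stdp_relative,
    perturb_c2c,
    sample_d2d,
    stdp_delta,
    stdp_relative,
    substream,
)


class TestStdpDelta:
    @pytest.mark.parametrize(
        "w, dt, expected",
        [
            # direct evaluation of the soft-bound rule at the defaults
            (30.0, 150.0, 1.0 * (50 - 30) * math.exp(-1.0)),
            (30.0, -150.0, -0.6 * (30 - 10) * math.exp(-1.0)),
            (50.0, 50.0, 0.0),   # at the ceiling: potentiation vanishes
            (10.0, -50.0, 0.0),  # at the floor: depression vanishes
        ],
    )
    def test_frozen_values(self, params, w, dt, expected):
        assert stdp_delta(w, dt, params) == pytest.approx(expected, abs=1e-12)

    def test_delta_t_zero_is_potentiation(self, params):
        # a same-step pre spike contributed to the firing
        assert stdp_delta(30.0, 0.0, params) == pytest.approx(20.0)

    def test_nonfinite_rejected(self, params):
        with pytest.raises(ValueError):
            stdp_delta(float("nan"), 150.0, params)
        with pytest.raises(ValueError):
            stdp_delta(30.0, float("inf"), params)

    @given(
        w=st.floats(10.0 + 1e-6, 50.0 - 1e-6),
        dt=st.floats(-1000.0, 1000.0).filter(lambda x: abs(x) > 1e-9),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_sign_matches_delta_t(self, w, dt):
        d = stdp_delta(w, dt, StdpParams())
        assert math.copysign(1.0, d) == math.copysign(1.0, dt)

    @given(w=st.floats(10.0, 49.0), dt=st.floats(1.0, 500.0),
           shrink=st.floats(1.0, 3.0))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_contraction_in_dt_and_w(self, w, dt, shrink):
        """|ΔW| strictly decreases with |Δt| and, for Δt>0, with w."""
        p = StdpParams()
        assert abs(stdp_delta(w, dt * shrink + 1.0, p)) < abs(stdp_delta(w, dt, p))
        assert stdp_delta(w + 0.5, dt, p) < stdp_delta(w, dt, p)


class TestRelativeRules:
    def test_soft_bound_relative_values(self, params):
        # (W_max/W − 1)·A+ in the Δt→0+ limit, at two measured device states
        assert stdp_relative(15.3, 1e-12, params) == pytest.approx(
            50 / 15.3 - 1, rel=1e-9)
        assert stdp_relative(45.1, 1e-12, params) == pytest.approx(
            50 / 45.1 - 1, rel=1e-9)

    def test_relative_vanishes_at_large_lag(self, params):
        assert stdp_relative(30.0, -1e6, params) == pytest.approx(0.0, abs=1e-12)

    def test_relative_requires_positive_weight(self, params):
        with pytest.raises(ValueError):
            stdp_relative(0.0, 50.0, params)

    def test_relative_is_delta_over_w(self, params):
        for w, dt in [(12.0, 75.0), (48.0, -30.0)]:
            assert stdp_relative(w, dt, params) == pytest.approx(
                stdp_delta(w, dt, params) / w)

    @pytest.mark.parametrize(
        "dt, expected",
        [(150.0, math.exp(-1.0)), (-150.0, -0.6 * math.exp(-1.0)), (0.0, 1.0)],
    )
    def test_classical_values(self, params, dt, expected):
        assert classical_stdp_relative(dt, params) == pytest.approx(expected)

    def test_classical_is_weight_independent_and_softbound_orders(self, params):
        """Classical ΔW/W ignores W; soft-bound potentiation ratio is larger
        for smaller W (the measured-device ordering)."""
        c = classical_stdp_relative(100.0, params)
        assert c == classical_stdp_relative(100.0, params)
        ws = [15.3, 25.1, 35.3, 45.1]
        ratios = [stdp_relative(w, 1e-9, params) for w in ws]
        assert all(a > b for a, b in zip(ratios, ratios[1:]))


class TestD2DSampling:
    def test_zero_variance_reproduces_nominal(self, params):
        arr = sample_d2d(params, VariationSpec(), 5, 4, seed=0)
        for name in ("a_plus", "a_minus", "w_max", "w_min"):
            assert np.all(arr.device_params[name] == getattr(params, name))
        assert not arr.stuck_mask.any()
        assert np.all(arr.weights >= params.w_min)
        assert np.all(arr.weights <= params.w_max)

    def test_defect_fraction_matches_closed_form(self, params):
        """Monte-Carlo fraction of devices with a negative amplitude at
        σ/μ = 0.5 equals 1 − Φ(2)² within 3 MC standard errors."""
        spec = VariationSpec(level_d2d=0.5, varied_params=("a_plus", "a_minus"))
        n = 400_000
        arr = sample_d2d(params, spec, 800, 500, seed=42)
        bad = (arr.device_params["a_plus"] < 0) | (arr.device_params["a_minus"] < 0)
        p_hat = bad.mean()
        p = 1 - norm.cdf(2.0) ** 2
        se = math.sqrt(p * (1 - p) / n)
        assert abs(p_hat - p) < 3 * se

    def test_swapped_bounds_become_stuck(self, params):
        spec = VariationSpec(level_d2d=0.5, varied_params=("w_max", "w_min"))
        arr = sample_d2d(params, spec, 300, 300, seed=7)
        swapped = arr.device_params["w_max"] <= arr.device_params["w_min"]
        assert swapped.any()
        assert np.all(arr.stuck_mask[swapped])

    def test_failure_rate_fraction_stuck(self, params):
        arr = sample_d2d(params, VariationSpec(failure_rate=0.3), 100, 100, seed=3)
        assert arr.stuck_mask.sum() == 3000

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            VariationSpec(failure_rate=1.5)
        with pytest.raises(ValueError):
            VariationSpec(level_d2d=-0.1)
        with pytest.raises(ValueError):
            VariationSpec(varied_params=("voltage",))


class TestC2C:
    def test_zero_level_is_identity(self, params, rng):
        assert perturb_c2c(params, VariationSpec(), rng) is params

    def test_negative_draw_fraction_and_dispersion(self, params):
        rng = substream(0, "c2c-test")
        spec = VariationSpec(level_c2c=0.5, varied_params=("a_plus",))
        draws = np.array([perturb_c2c(params, spec, rng).a_plus
                          for _ in range(20_000)])
        p = norm.cdf(-2.0)
        se = math.sqrt(p * (1 - p) / draws.size)
        assert abs((draws < 0).mean() - p) < 3 * se
        spec01 = VariationSpec(level_c2c=0.1, varied_params=("a_plus",))
        d01 = np.array([perturb_c2c(params, spec01, rng).a_plus
                        for _ in range(20_000)])
        assert d01.std() / d01.mean() == pytest.approx(0.1, rel=0.05)


class TestApplyUpdate:
    def test_stuck_synapse_is_noop(self, params):
        arr = sample_d2d(params, VariationSpec(failure_rate=1.0), 2, 2, seed=0)
        w0 = arr.weights.copy()
        apply_update(arr, 0, 0, 150.0)
        assert np.array_equal(arr.weights, w0)
        assert arr.update_counts.sum() == 0

    def test_unvaried_update_matches_rule(self, params):
        arr = sample_d2d(params, VariationSpec(), 1, 1, seed=0)
        arr.weights[0, 0] = 30.0
        apply_update(arr, 0, 0, 150.0)
        assert arr.weights[0, 0] == pytest.approx(30.0 + 20 * math.exp(-1.0))
        assert arr.update_counts[0, 0] == 1

    def test_repeated_potentiation_converges_to_ceiling(self, params):
        arr = sample_d2d(params, VariationSpec(), 1, 1, seed=0)
        arr.weights[0, 0] = params.w_min
        seq = []
        for _ in range(60):
            apply_update(arr, 0, 0, 50.0)
            seq.append(arr.weights[0, 0])
        assert all(b >= a for a, b in zip(seq, seq[1:]))
        assert seq[-1] == pytest.approx(params.w_max, abs=1e-6)
        assert arr.update_counts[0, 0] == 60

    def test_out_of_range_index(self, params):
        arr = sample_d2d(params, VariationSpec(), 2, 2, seed=0)
        with pytest.raises(IndexError):
            apply_update(arr, 5, 0, 100.0)

    @given(data=st.data())
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_bound_safety_without_variation(self, data):
        """Any update sequence without variation keeps weights in
        [w_min, w_max] exactly."""
        p = StdpParams()
        arr = sample_d2d(p, VariationSpec(), 3, 2, seed=1)
        n = data.draw(st.integers(1, 30))
        for _ in range(n):
            i = data.draw(st.integers(0, 2))
            j = data.draw(st.integers(0, 1))
            dt = data.draw(st.floats(-400.0, 400.0))
            apply_update(arr, i, j, dt)
        assert np.all(arr.weights >= p.w_min - 1e-12)
        assert np.all(arr.weights <= p.w_max + 1e-12)

    def test_seeded_trajectories_are_bitwise_identical(self, params):
        spec = VariationSpec(level_c2c=0.3, level_d2d=0.3)
        runs = []
        for _ in range(2):
            arr = sample_d2d(params, spec, 4, 3, seed=11)
            for k in range(25):
                apply_update(arr, k % 4, k % 3, 50.0 if k % 2 else -100.0)
            runs.append(arr.weights.copy())
        assert np.array_equal(runs[0], runs[1])
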