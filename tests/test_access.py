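"""Access-to-care estimation: stepped mapping, smooth curve, adjustments."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import betainc

from mgdb import (
    AccessCurve,
    MortalityInputs,
    adjust_imr_consanguinity,
    consanguinity_imr,
    estimate_access,
    final_adjusted_imr,
    fit_access_curve,
    stepped_access,
)
from mgdb.config import AccessConfig, ConsanguinityConfig
from mgdb.errors import CalibrationError, InputError


class TestSteppedAccess:
    @pytest.mark.parametrize(
        "imr, expected",
        [
            (0.0, 1.00), (8.0, 1.00), (9.99, 1.00),
            (10.0, 0.50), (17.0, 0.50), (24.9, 0.50),
            (25.0, 0.15), (39.5, 0.15), (54.9, 0.15),
            (55.0, 0.05), (77.0, 0.05), (99.9, 0.05),
            (100.0, 0.00), (120.0, 0.00), (1e6, 0.00),
        ],
    )
    def test_band_values(self, imr, expected):
        assert stepped_access(imr) == expected

    @pytest.mark.parametrize("bad", [-1.0, float("nan"), float("inf")])
    def test_invalid_imr_rejected(self, bad):
        with pytest.raises(InputError):
            stepped_access(bad)

    @given(st.floats(min_value=0, max_value=500))
    def test_value_set_and_monotonicity(self, imr):
        v = stepped_access(imr)
        assert v in {1.0, 0.5, 0.15, 0.05, 0.0}
        assert stepped_access(imr + 1.0) <= v


class TestAccessCurve:
    def test_endpoints_clamped(self, curve):
        assert curve(9.0) == 1.0
        assert curve(0.0) == 1.0
        assert curve(100.0) == 0.0
        assert curve(150.0) == 0.0

    def test_anchors_within_tolerance(self, curve):
        for m, target in [(17, 0.50), (39.5, 0.15), (77, 0.05)]:
            assert abs(curve(m) - target) <= 0.05

    def test_monotone_nonincreasing_on_grid(self, curve):
        grid = np.linspace(0, 150, 1000)
        vals = curve(grid)
        assert np.all(np.diff(vals) <= 1e-12)
        assert np.all((0 <= vals) & (vals <= 1))

    def test_strictly_decreasing_interior(self, curve):
        grid = np.linspace(9.5, 99.5, 200)
        assert np.all(np.diff(curve(grid)) < 0)

    def test_fit_beats_grid_search_oracle(self, curve):
        """Least-squares fit is at least as good as a dense grid search."""
        anchors = [(17, 0.50), (39.5, 0.15), (77, 0.05)]

        def sse(a, b):
            return sum(
                (1 - betainc(a, b, (m - 9) / 91) - t) ** 2 for m, t in anchors
            )

        grid = np.exp(np.linspace(np.log(0.05), np.log(20), 60))
        best = min(sse(a, b) for a in grid for b in grid)
        assert sse(curve.shape_a, curve.shape_b) <= best + 1e-9

    def test_unreachable_anchors_raise_calibration_error(self):
        cfg = AccessConfig(anchors=[(17, 0.9), (39.5, 0.05), (77, 0.7)])
        with pytest.raises(CalibrationError):
            fit_access_curve(config=cfg)

    def test_invalid_shape_parameters_rejected(self):
        with pytest.raises(InputError):
            AccessCurve(m_lo=9, m_hi=100, shape_a=-1, shape_b=2)
        with pytest.raises(InputError):
            AccessCurve(m_lo=100, m_hi=9, shape_a=1, shape_b=2)


class TestConsanguinityImr:
    def test_zero_alpha_gives_zero(self):
        assert consanguinity_imr(0.0, 0.5) == 0.0

    def test_reference_level_identity(self):
        m = ConsanguinityConfig(e_nocare=30.0)
        assert consanguinity_imr(0.0625, 0.0, m) == pytest.approx(30.0)

    def test_hand_arithmetic(self):
        m = ConsanguinityConfig(e_nocare=30.0, rho=0.8)
        assert consanguinity_imr(0.02, 0.5, m) == pytest.approx(5.76)

    def test_linear_in_alpha_decreasing_in_access(self):
        m = ConsanguinityConfig()
        assert consanguinity_imr(0.04, 0.3, m) == pytest.approx(
            2 * consanguinity_imr(0.02, 0.3, m)
        )
        assert consanguinity_imr(0.02, 0.9, m) < consanguinity_imr(0.02, 0.1, m)


class TestIterativeAdjustment:
    def test_zero_alpha_is_identity(self, curve):
        est = adjust_imr_consanguinity(MortalityInputs(imr=30.0), curve)
        assert est.adjusted_imr == 30.0
        accesses = [a for _, _, a in est.iteration_trace]
        assert all(a == est.access_unadjusted for a in accesses)

    def test_second_iteration_undoes_over_reduction(self, curve):
        est = adjust_imr_consanguinity(MortalityInputs(imr=40.0, alpha=0.025), curve)
        imr1, imr2 = est.iteration_trace[0][1], est.iteration_trace[1][1]
        assert imr1 < imr2 < 40.0

    def test_default_iteration_count_is_two(self, curve):
        est = adjust_imr_consanguinity(MortalityInputs(imr=22.0, alpha=0.03), curve)
        assert len(est.iteration_trace) == 2

    def test_over_reduction_correction_sweep(self, curve):
        for alpha in [0.005, 0.01, 0.02, 0.03, 0.04]:
            for imr in [10, 20, 30, 40, 50, 60]:
                est = adjust_imr_consanguinity(
                    MortalityInputs(imr=float(imr), alpha=alpha), curve
                )
                imr1, imr2 = est.iteration_trace[0][1], est.iteration_trace[1][1]
                assert imr2 >= imr1 - 1e-12, (alpha, imr)

    def test_many_iterations_match_fixed_point_oracle(self, curve):
        """The n_iter→∞ trace limit equals a brute-force fixed-point solve."""
        m = ConsanguinityConfig(n_iter=80)
        for imr, alpha in [(15, 0.03), (30, 0.02), (45, 0.04), (80, 0.01)]:
            est = adjust_imr_consanguinity(MortalityInputs(imr=imr, alpha=alpha), curve, m)
            # independent fixed-point solve on access
            a, floor = curve(imr), m.imr_floor
            for _ in range(10_000):
                adj = max(imr - consanguinity_imr(alpha, a, m), floor)
                a_new = curve(adj)
                if abs(a_new - a) < 1e-9:
                    break
                a = a_new
            assert est.adjusted_imr == pytest.approx(adj, abs=1e-6)


class TestFinalAdjustment:
    def test_hiv_subtraction(self):
        assert final_adjusted_imr(41.25, 0.05) == pytest.approx(41.20)

    def test_zero_hiv_identity(self):
        assert final_adjusted_imr(30.0, 0.0) == 30.0

    def test_clamped_at_floor_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="mgdb.access"):
            assert final_adjusted_imr(5.0, 10.0, imr_floor=1.0) == 1.0
        assert any("clamp" in r.message for r in caplog.records)

    def test_negative_inputs_rejected(self):
        with pytest.raises(InputError):
            final_adjusted_imr(-1.0, 0.0)


class TestEstimateAccess:
    def test_no_adjustment_no_change(self, curve):
        est = estimate_access(MortalityInputs(imr=30.0), curve)
        assert est.access_final == est.access_unadjusted

    def test_adjustments_raise_access(self, curve):
        est = estimate_access(MortalityInputs(imr=45.0, alpha=0.03), curve)
        assert est.access_final > est.access_unadjusted

    def test_low_imr_full_access(self, curve):
        est = estimate_access(MortalityInputs(imr=4.0, alpha=0.02, hiv_imr=1.0), curve)
        assert est.access_final == 1.0

    def test_adjusted_imr_ordering(self, curve):
        est = estimate_access(MortalityInputs(imr=50.0, alpha=0.03, hiv_imr=2.0), curve)
        assert est.final_adjusted_imr <= est.adjusted_imr <= 50.0
        assert 0 <= est.access_final <= 1

    def test_access_gain_peaks_in_development_window(self, curve):
        """The consanguinity adjustment matters most on the steep part of
        the development curve (IMR between 10 and 35 per 1000)."""
        imrs = np.arange(2.0, 121.0, 1.0)
        gains = []
        for imr in imrs:
            est = estimate_access(MortalityInputs(imr=imr, alpha=0.03), curve)
            gains.append(est.access_final - est.access_unadjusted)
        peak = imrs[int(np.argmax(gains))]
        assert 10 <= peak <= 35

    @settings(max_examples=50, deadline=None)
    @given(
        imr=st.floats(min_value=0, max_value=150),
        alpha=st.floats(min_value=0, max_value=0.0625),
        hiv_frac=st.floats(min_value=0, max_value=1),
    )
    def test_access_never_decreases_under_adjustment(self, curve, imr, alpha, hiv_frac):
        est = estimate_access(
            MortalityInputs(imr=imr, alpha=alpha, hiv_imr=hiv_frac * imr), curve
        )
        assert est.access_final >= est.access_unadjusted - 1e-12


class TestMortalityInputsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"imr": -1},
            {"imr": math.nan},
            {"imr": 10, "hiv_imr": 11},
            {"imr": 10, "alpha": 0.1},
            {"imr": 10, "alpha": -0.01},
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(InputError):
            MortalityInputs(**kwargs)
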