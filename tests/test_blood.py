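import numpy as np
import pytest
from hypothesis import given, strategies as st

from petkin import (
    ParentFractionFit,
    SampledCurve,
    build_parent_plasma_input,
    calibrate_continuous,
    estimate_delay,
    fit_parent_fraction,
    plasma_over_blood,
)
from petkin.synthetic import SyntheticConfig


class TestPlasmaOverBlood:
    @pytest.mark.parametrize(
        "samples, expected",
        [
            ([(1.14, 1.0)], 1.14),
            ([(2.0, 2.0), (3.0, 3.0)], 1.0),
            ([(1.0, 1.0), (1.2, 1.0)], 1.1),
        ],
    )
    def test_mean_of_ratios(self, samples, expected):
        assert plasma_over_blood(samples) == pytest.approx(expected, rel=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            plasma_over_blood([])
        with pytest.raises(ValueError):
            plasma_over_blood([(1.0, 0.0)])


class TestParentFractionFit:
    def test_exact_recovery_of_generating_parameters(self):
        truth = ParentFractionFit(A=0.65, alpha=0.5, beta=0.04)
        t = np.array([4.0, 6.0, 8.0, 12.0, 20.0, 30.0])
        fit = fit_parent_fraction(np.column_stack([t, truth(t)]))
        assert fit.A == pytest.approx(0.65, abs=1e-6)
        assert fit.alpha == pytest.approx(0.5, abs=1e-6)
        assert fit.beta == pytest.approx(0.04, abs=1e-6)

    def test_all_ones_fits_constant_unity(self):
        t = np.array([4.0, 6.0, 8.0, 12.0, 20.0, 30.0])
        fit = fit_parent_fraction(np.column_stack([t, np.ones_like(t)]))
        grid = np.linspace(0, 30, 200)
        np.testing.assert_allclose(fit(grid), 1.0, atol=1e-6)

    def test_default_truth_below_half_by_four_minutes(self):
        cfg = SyntheticConfig()
        pf = ParentFractionFit(A=cfg.pf_A, alpha=cfg.pf_alpha, beta=cfg.pf_beta)
        assert pf(np.array([4.0]))[0] < 0.5

    def test_requires_three_samples(self):
        with pytest.raises(ValueError):
            fit_parent_fraction([(4.0, 0.9), (8.0, 0.5)])

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            fit_parent_fraction([(4.0, 0.9), (8.0, np.nan), (12.0, 0.3)])

    def test_starts_at_unity(self):
        pf = ParentFractionFit(A=0.3, alpha=1.0, beta=0.02)
        assert pf(np.array([0.0]))[0] == 1.0

    @given(st.floats(0, 1), st.floats(0.0, 5.0), st.floats(0.0, 5.0))
    def test_monotone_nonincreasing(self, A, r1, r2):
        pf = ParentFractionFit(A=A, alpha=max(r1, r2), beta=min(r1, r2))
        t = np.linspace(0, 30, 100)
        f = pf(t)
        assert np.all(np.diff(f) <= 1e-12)
        assert np.all((f >= 0) & (f <= 1))


class TestEstimateDelay:
    @pytest.mark.parametrize("true_delay", [10.0, -7.0, 0.0])
    def test_self_shift_recovery(self, bolus_curve_5min, true_delay):
        shifted = bolus_curve_5min.shifted(true_delay)
        est = estimate_delay(shifted, bolus_curve_5min)
        assert est == pytest.approx(true_delay, abs=1.0)

    def test_antisymmetry(self, bolus_curve_5min):
        shifted = bolus_curve_5min.shifted(9.0)
        fwd = estimate_delay(shifted, bolus_curve_5min)
        rev = estimate_delay(bolus_curve_5min, shifted)
        assert fwd == pytest.approx(-rev, abs=1.0)

    def test_flat_curve_rejected(self, bolus_curve_5min):
        flat = SampledCurve(bolus_curve_5min.times,
                            np.full_like(bolus_curve_5min.values, 3.0))
        with pytest.raises(ValueError):
            estimate_delay(flat, bolus_curve_5min)


class TestBuildParentPlasmaInput:
    def test_identity_when_all_factors_unity(self, bolus_curve_30min):
        pf = ParentFractionFit(A=0.0, alpha=0.0, beta=0.0)  # f == 1
        inp = build_parent_plasma_input(bolus_curve_30min, 1.0, pf, 0.0)
        np.testing.assert_allclose(inp.parent_plasma.values,
                                   bolus_curve_30min.values, rtol=1e-12)

    def test_pob_and_fraction_cancel(self, bolus_curve_30min):
        # constant parent fraction 0.5: realised by A=1 with alpha=0 scaled via pob
        pf = ParentFractionFit(A=0.0, alpha=0.0, beta=0.0)
        inp = build_parent_plasma_input(bolus_curve_30min, 2.0, pf, 0.0)
        np.testing.assert_allclose(0.5 * inp.parent_plasma.values,
                                   bolus_curve_30min.values, rtol=1e-12)

    def test_pointwise_product_oracle(self, bolus_curve_30min):
        pf = ParentFractionFit(A=0.65, alpha=0.5, beta=0.04)
        inp = build_parent_plasma_input(bolus_curve_30min, 1.14, pf, 0.0)
        expected = 1.14 * pf(bolus_curve_30min.times) * bolus_curve_30min.values
        np.testing.assert_allclose(inp.parent_plasma.values, expected, rtol=1e-12)

    def test_linear_in_whole_blood_amplitude(self, bolus_curve_30min):
        pf = ParentFractionFit(A=0.65, alpha=0.5, beta=0.04)
        doubled = SampledCurve(bolus_curve_30min.times, 2.0 * bolus_curve_30min.values)
        a = build_parent_plasma_input(bolus_curve_30min, 1.14, pf, 3.0)
        b = build_parent_plasma_input(doubled, 1.14, pf, 3.0)
        np.testing.assert_allclose(b.parent_plasma.values,
                                   2.0 * a.parent_plasma.values, rtol=1e-12)

    def test_delay_correction_realigns(self, bolus_curve_30min):
        # a blood record lagging by 10 s, corrected with delay=+10, matches truth
        pf = ParentFractionFit(A=0.0, alpha=0.0, beta=0.0)
        lagged = SampledCurve(
            bolus_curve_30min.times,
            bolus_curve_30min(bolus_curve_30min.times - 10.0 / 60.0),
        )
        inp = build_parent_plasma_input(lagged, 1.0, pf, delay_s=10.0)
        mid = slice(100, 1500)  # away from the grid edges
        np.testing.assert_allclose(inp.parent_plasma.values[mid],
                                   bolus_curve_30min.values[mid], rtol=1e-9, atol=1e-9)


class TestCalibrateContinuous:
    def test_scale_recovery_and_extension(self, bolus_curve_30min):
        t = bolus_curve_30min.times
        keep = t <= 15.0
        detector = SampledCurve(t[keep], 0.85 * bolus_curve_30min.values[keep])
        manual_t = np.array([4.0, 6.0, 8.0, 12.0, 20.0, 30.0])
        manual = SampledCurve(manual_t, bolus_curve_30min(manual_t))
        cal = calibrate_continuous(detector, manual, scan_end_min=30.0)
        assert cal.times[-1] == pytest.approx(30.0, abs=1e-6)
        # scale undone where the continuous record exists
        np.testing.assert_allclose(cal.values[: keep.sum()],
                                   bolus_curve_30min.values[keep], rtol=1e-9)
        # extrapolated tail is positive and close to the true curve
        tail = cal(np.array([25.0]))[0]
        assert tail == pytest.approx(bolus_curve_30min(np.array([25.0]))[0], rel=0.1)

    def test_no_overlap_rejected(self, bolus_curve_30min):
        t = bolus_curve_30min.times
        keep = t <= 2.0
        detector = SampledCurve(t[keep], bolus_curve_30min.values[keep])
        manual = SampledCurve(np.array([20.0, 30.0]), np.array([5.0, 3.0]))
        with pytest.raises(ValueError):
            calibrate_continuous(detector, manual, scan_end_min=30.0)
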