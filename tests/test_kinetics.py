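import numpy as np
import pytest
from scipy.integrate import solve_ivp

from petkin import (
    CANDIDATE_MODELS,
    N13,
    O15,
    InputFunction,
    KineticParams,
    ModelSpec,
    SampledCurve,
    fit_compartment_model,
    fit_meyer_cbf,
    frame_weights,
    make_schedule,
    simulate_tissue_curve,
)
from petkin.kinetics import expconv
from petkin.synthetic import add_frame_noise


class TestFrameWeights:
    def test_single_frame(self):
        sched = make_schedule([(1, 60)])
        np.testing.assert_allclose(frame_weights(sched, N13), [1.0])

    def test_later_equal_frame_weighs_less(self):
        sched = make_schedule([(2, 60)])
        w = frame_weights(sched, N13)
        assert w[1] < w[0]
        assert w.sum() == pytest.approx(1.0)

    def test_zero_decay_limit_proportional_to_duration(self):
        from petkin import Isotope
        stable = Isotope("stable", 1e12)
        sched = make_schedule([(1, 10), (1, 30)])
        w = frame_weights(sched, stable)
        np.testing.assert_allclose(w, [0.25, 0.75], rtol=1e-6)


class TestExpconv:
    def test_against_quadrature(self):
        t = np.linspace(0, 10, 601)
        u = np.exp(-0.3 * t) * t
        for rate in (0.0, 0.05, 1.3):
            got = expconv(t, u, rate)
            # independent brute force on the same piecewise-linear input
            ref = np.empty_like(t)
            for i, ti in enumerate(t):
                s = np.linspace(0, ti, 2001)
                ref[i] = np.trapezoid(np.exp(-rate * (ti - s)) * np.interp(s, t, u), s)
            np.testing.assert_allclose(got, ref, atol=1e-5 * max(ref.max(), 1))

    def test_nonuniform_grid_against_quadrature(self):
        # jittered spacing forces the sequential recurrence path
        rng = np.random.default_rng(1)
        t = np.sort(np.concatenate([[0.0, 5.0], rng.uniform(0, 5, 150)]))
        u = np.exp(-0.3 * t) * t
        got = expconv(t, u, 0.7)
        ref = np.empty_like(t)
        for i, ti in enumerate(t):
            s = np.linspace(0, ti, 4001)
            ref[i] = np.trapezoid(np.exp(-0.7 * (ti - s)) * np.interp(s, t, u), s)
        np.testing.assert_allclose(got, ref, atol=1e-5 * max(ref.max(), 1))


class TestForwardModel:
    def test_zero_delivery_gives_zero_curve(self, ammonia_input, ammonia_schedule):
        params = KineticParams(K1=0.0, vB=0.0)
        tac = simulate_tissue_curve(params, CANDIDATE_MODELS["1tcm_irr"],
                                    ammonia_input, ammonia_schedule)
        np.testing.assert_array_equal(tac, 0.0)

    def test_constant_input_linear_accumulation(self):
        # irreversible 1TCM with constant Cp=c: C_PET(t) = (K1/100) c t exactly
        t = np.arange(0, 30 + 1 / 120, 1 / 60)
        const = SampledCurve(t, np.full_like(t, 5.0))
        inp = InputFunction(const, const, 1.0)
        sched = make_schedule([(30, 60)])
        tac = simulate_tissue_curve(KineticParams(K1=20.0, vB=0.0),
                                    CANDIDATE_MODELS["1tcm_irr"], inp, sched)
        expected = (20.0 / 100.0) * 5.0 * sched.mids  # frame mean of a linear curve
        np.testing.assert_allclose(tac, expected, rtol=1e-8)

    def test_nesting_identity_2tcm_reduces_to_1tcm(self, ammonia_input, ammonia_schedule):
        p = KineticParams(K1=20.0, k2=0.05, k3=0.0, k4=0.0, vB=0.04)
        two = simulate_tissue_curve(p, CANDIDATE_MODELS["2tcm_rev"],
                                    ammonia_input, ammonia_schedule)
        one = simulate_tissue_curve(p, CANDIDATE_MODELS["1tcm_rev"],
                                    ammonia_input, ammonia_schedule)
        np.testing.assert_allclose(two, one, atol=1e-10 * one.max())

    def test_against_stiff_ode_oracle(self, ammonia_input):
        params = KineticParams(K1=25.0, k2=0.3, k3=0.08, k4=0.02, vB=0.0)
        cp = ammonia_input.parent_plasma
        fine = simulate_tissue_curve(params, CANDIDATE_MODELS["2tcm_rev"],
                                     ammonia_input, make_schedule([(30, 60)]), fine=True)

        def rhs(t, y):
            cpt = np.interp(t, cp.times, cp.values)
            c1, c2 = y
            return [params.K1 / 100 * cpt - (params.k2 + params.k3) * c1 + params.k4 * c2,
                    params.k3 * c1 - params.k4 * c2]

        t_eval = cp.times[::30]  # every 30 s
        sol = solve_ivp(rhs, (0, cp.times[-1]), [0.0, 0.0], method="BDF",
                        t_eval=t_eval, rtol=1e-10, atol=1e-12, max_step=1.0 / 60)
        oracle = sol.y.sum(axis=0)
        ours = np.interp(t_eval, cp.times, fine)
        assert np.max(np.abs(ours - oracle)) / oracle.max() < 1e-6

    def test_nonnegative_output(self, ammonia_input, ammonia_schedule):
        params = KineticParams(K1=15.0, k2=0.4, k3=0.1, k4=0.05, vB=0.1)
        tac = simulate_tissue_curve(params, CANDIDATE_MODELS["2tcm_rev"],
                                    ammonia_input, ammonia_schedule)
        assert np.all(tac >= 0)


TRUE_BY_MODEL = {
    "1tcm_irr": KineticParams(K1=20.0, vB=0.05),
    "1tcm_rev": KineticParams(K1=20.0, k2=0.007, vB=0.05),
    "2tcm_irr": KineticParams(K1=20.0, k2=0.2, k3=0.05, vB=0.03),
    "2tcm_rev": KineticParams(K1=20.0, k2=0.2, k3=0.05, k4=0.01, vB=0.03),
}


class TestFitting:
    @pytest.mark.parametrize("model_id", list(CANDIDATE_MODELS))
    def test_noiseless_round_trip(self, model_id, ammonia_input, ammonia_schedule):
        spec = CANDIDATE_MODELS[model_id]
        truth = TRUE_BY_MODEL[model_id]
        tac = simulate_tissue_curve(truth, spec, ammonia_input, ammonia_schedule)
        w = frame_weights(ammonia_schedule, N13)
        fit = fit_compartment_model(tac, ammonia_schedule, ammonia_input, spec, weights=w)
        assert fit.converged
        for name in spec.param_names:
            got = getattr(fit.params, name)
            want = getattr(truth, name)
            assert got == pytest.approx(want, rel=5e-3), name

    def test_reversible_1tcm_tight_recovery(self, ammonia_input, ammonia_schedule):
        truth = KineticParams(K1=20.0, k2=0.007, vB=0.05)
        spec = CANDIDATE_MODELS["1tcm_rev"]
        tac = simulate_tissue_curve(truth, spec, ammonia_input, ammonia_schedule)
        fit = fit_compartment_model(tac, ammonia_schedule, ammonia_input, spec,
                                    weights=frame_weights(ammonia_schedule, N13))
        assert fit.params.K1 == pytest.approx(20.0, rel=1e-3)
        assert fit.params.k2 == pytest.approx(0.007, rel=1e-3)
        assert fit.params.vB == pytest.approx(0.05, rel=1e-3)

    def test_zero_tac_drives_parameters_to_zero(self, ammonia_input, ammonia_schedule):
        tac = np.zeros(ammonia_schedule.n_frames)
        fit = fit_compartment_model(tac, ammonia_schedule, ammonia_input,
                                    CANDIDATE_MODELS["1tcm_rev"])
        assert fit.params.K1 == pytest.approx(0.0, abs=1e-6)
        assert fit.params.vB == pytest.approx(0.0, abs=1e-6)

    def test_wrss_never_increases_when_freeing_nested_parameter(
            self, ammonia_input, ammonia_schedule):
        truth = KineticParams(K1=20.0, k2=0.02, vB=0.05)
        clean = simulate_tissue_curve(truth, CANDIDATE_MODELS["1tcm_rev"],
                                      ammonia_input, ammonia_schedule)
        rng = np.random.default_rng(7)
        noisy = add_frame_noise(clean, ammonia_schedule, N13, 0.05, rng).values
        from petkin import fit_candidate_models

        w = frame_weights(ammonia_schedule, N13)
        for tac in (clean, noisy):
            fits = fit_candidate_models(tac, ammonia_schedule, ammonia_input, weights=w)
            wrss = [fits[m].wrss for m in ("1tcm_irr", "1tcm_rev", "2tcm_irr", "2tcm_rev")]
            for simpler, complexer in zip(wrss[:-1], wrss[1:]):
                assert complexer <= simpler * (1 + 1e-8) + 1e-12

    def test_k1_bias_small_over_noisy_replicates(self, ammonia_input, ammonia_schedule):
        """Median relative K1 bias < 2% across 100 noisy reversible-1TCM fits."""
        truth = KineticParams(K1=20.1, k2=0.0069, vB=0.05)
        spec = CANDIDATE_MODELS["1tcm_rev"]
        clean = simulate_tissue_curve(truth, spec, ammonia_input, ammonia_schedule)
        w = frame_weights(ammonia_schedule, N13)
        rng = np.random.default_rng(42)
        rel = []
        for _ in range(100):
            noisy = add_frame_noise(clean, ammonia_schedule, N13, 0.05, rng).values
            fit = fit_compartment_model(noisy, ammonia_schedule, ammonia_input,
                                        spec, weights=w, n_starts=3)
            rel.append((fit.params.K1 - truth.K1) / truth.K1)
        assert abs(np.median(rel)) < 0.02


class TestMeyerCBF:
    def test_noiseless_recovery(self, water_input, water_schedule):
        spec = ModelSpec(1, reversible=True, fit_vB=True, fit_delay_dispersion=True)
        truth = KineticParams(K1=37.6, k2=0.42, vB=0.04, delay_s=5.0, tau_s=4.0)
        tac = simulate_tissue_curve(truth, spec, water_input, water_schedule)
        res = fit_meyer_cbf(tac, water_input.whole_blood, water_schedule,
                            weights=frame_weights(water_schedule, O15))
        assert res.converged
        assert res.CBF == pytest.approx(37.6, rel=0.01)
        assert res.k2p == pytest.approx(0.42, rel=0.01)
        assert res.delay_s == pytest.approx(5.0, abs=0.1)
        assert res.tau_s == pytest.approx(4.0, abs=0.1)

    def test_reduces_to_reversible_1tcm_without_delay_dispersion(
            self, water_input, water_schedule):
        p = KineticParams(K1=37.6, k2=0.42, vB=0.04, delay_s=0.0, tau_s=0.0)
        dd_spec = ModelSpec(1, True, True, True)
        plain = CANDIDATE_MODELS["1tcm_rev"]
        a = simulate_tissue_curve(p, dd_spec, water_input, water_schedule)
        b = simulate_tissue_curve(p, plain, water_input, water_schedule)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_zero_flow_zero_curve(self, water_input, water_schedule):
        p = KineticParams(K1=0.0, k2=0.0, vB=0.0)
        tac = simulate_tissue_curve(p, ModelSpec(1, True, True, True),
                                    water_input, water_schedule)
        np.testing.assert_array_equal(tac, 0.0)
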