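"""Transient simulation, steady states, convergence times, memory, hysteresis."""

import numpy as np
import pytest

from alleesense import (AnalyteProfile, alpha_bounds, convergence_time,
                        dist_amp_steady_state, dose_response, find_equilibria,
                        find_sigma_c, hysteresis_sweep, integrate,
                        memory_experiment, steady_state, table2_summary)


class TestIntegrate:
    def test_equilibrium_initial_condition_stays_put(self, params):
        traj = integrate("allee", params, 0.0, H0=0.0, t_end=2.0)
        assert np.all(np.abs(traj.H) < 1.0)

    def test_high_rate_transient_reaches_printed_density(self, params):
        traj = integrate("allee", params, 4.0, H0=0.0, t_end=2.0)
        assert traj.final_H == pytest.approx(1.01e8, abs=0.02 * params.P)

    def test_broadcast_amplifies_arbitrarily_small_rate(self, params):
        traj = integrate("broadcast", params, 1e-3, H0=0.0, t_end=5.0)
        assert traj.final_H == pytest.approx(params.P, rel=1e-3)

    @pytest.mark.parametrize("model", ["allee", "set_reset", "broadcast"])
    @pytest.mark.parametrize("sigma", [0.0, 1.5, 5.0])
    def test_population_conservation(self, params, model, sigma):
        traj = integrate(model, params, sigma, H0=0.3 * params.P, t_end=3.0)
        assert np.all(traj.H >= -1e-6 * params.P)
        assert np.all(traj.H <= params.P * (1 + 1e-6))
        assert np.all(np.diff(traj.times) > 0)

    def test_profile_drive_resolves_sigma_segments(self, params):
        prof = AnalyteProfile.pulse(2.0, t_start=1.0, width=0.5)
        traj = integrate("allee", params, prof, t_end=3.0)
        inside = (traj.times > 1.0) & (traj.times < 1.5)
        outside = traj.times > 1.6
        assert np.all(traj.sigma[inside] == 2.0 * params.sigma_A)
        assert np.all(traj.sigma[outside] == params.sigma_err)

    def test_invalid_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            integrate("nonsense", params, 1.0, t_end=1.0)
        with pytest.raises(ValueError):
            integrate("allee", params, 1.0, H0=-1.0, t_end=1.0)
        with pytest.raises(ValueError):
            integrate("allee", params, -1.0, t_end=1.0)
        with pytest.raises(ValueError):
            integrate("allee", params, 1.0, t_end=0.0)


class TestSteadyState:
    def test_set_reset_closed_form(self, params):
        res = steady_state("set_reset", params, params.rho)
        assert res.converged
        assert res.value == pytest.approx(params.P / 2, rel=1e-6)
        for s in (0.7, 3.0, 11.0):
            assert steady_state("set_reset", params, s).value == pytest.approx(
                params.P * s / (params.rho + s), rel=1e-6)

    def test_allee_matches_equilibrium_roots(self, params):
        for s in (0.0, 1.5, 4.0, 5.0):
            res = steady_state("allee", params, s)
            assert res.converged
            assert res.value == pytest.approx(res.nearest_root,
                                              abs=5e-3 * params.P)

    def test_dist_amp_matches_closed_form(self, params):
        res = steady_state("dist_amp", params, 2.0)
        ref = dist_amp_steady_state(2.0, params)
        assert res.value == pytest.approx(ref.H, rel=1e-4)
        assert res.S == pytest.approx(ref.S, rel=1e-3)


class TestConvergenceTime:
    def test_zero_steady_state_converges_immediately(self, params):
        traj = integrate("allee", params, 0.0, t_end=1.0)
        assert convergence_time(traj, 0.0) == 0.0

    def test_linear_model_closed_form(self, params):
        # without feedback H(t) = H_ss (1 - e^{-(sigma+rho)t}), so the 95%
        # time is ln(20)/(sigma+rho)
        sigma = 6.0
        traj = integrate("set_reset", params, sigma, t_end=2.0, n_points=8001)
        H_ss = params.P * sigma / (params.rho + sigma)
        expected = np.log(20.0) / (sigma + params.rho)
        assert convergence_time(traj, H_ss) == pytest.approx(expected, rel=1e-3)

    def test_unreached_threshold_raises(self, params):
        traj = integrate("allee", params, 1.5, t_end=0.01)
        with pytest.raises(ValueError):
            convergence_time(traj, 1.03e8)

    def test_insensitive_to_solver_tolerance(self, params):
        ref = integrate("allee", params, 1.5, t_end=2.0, n_points=8001)
        tight = integrate("allee", params, 1.5, t_end=2.0, n_points=8001,
                          rtol=1e-10, atol=0.1)
        steady = find_equilibria(1.5, params).roots[0]
        t_ref = convergence_time(ref, steady)
        t_tight = convergence_time(tight, steady)
        assert t_tight == pytest.approx(t_ref, rel=1e-3)


class TestTable2Summary:
    def test_columns_and_zero_row(self, params):
        df = table2_summary(params, sigmas=(0.0, 1.5))
        assert list(df.columns) == ["sigma", "steady_state",
                                    "convergence_time", "terminal_H"]
        row0 = df.iloc[0]
        assert row0.steady_state == 0.0 and row0.convergence_time == 0.0


class TestMemory:
    def test_zero_amplitude_is_not_memorized(self, params):
        out = memory_experiment(params, AnalyteProfile.constant(0.0))
        assert not out.memorized
        assert out.final_H == pytest.approx(0.0, abs=1.0)

    def test_long_supercritical_step_is_memorized(self, params):
        sc = find_sigma_c(params).sigma_c
        prof = AnalyteProfile.step_down((sc + 1.0) / params.sigma_A, t_step=2.0)
        out = memory_experiment(params, prof)
        _, alpha_f = alpha_bounds(params)
        assert out.memorized and out.final_H >= alpha_f * params.P

    def test_short_pulse_is_forgotten(self, params):
        out = memory_experiment(params,
                                AnalyteProfile.pulse(2.0, t_start=0.1, width=0.5))
        alpha_i, _ = alpha_bounds(params)
        assert not out.memorized
        assert out.final_H < alpha_i * params.P

    def test_minimal_memorizing_amplitude_brackets_sigma_c(self, params):
        # bisect the step amplitude at a long fixed exposure: the threshold
        # amplitude must sit just above sigma_c / sigma_A
        sc = find_sigma_c(params).sigma_c
        lo, hi = 2.0, 4.0
        for _ in range(9):
            mid = 0.5 * (lo + hi)
            out = memory_experiment(params,
                                    AnalyteProfile.step_down(mid, t_step=5.0))
            lo, hi = (lo, mid) if out.memorized else (mid, hi)
        threshold = 0.5 * (lo + hi)
        assert sc / params.sigma_A <= threshold <= sc / params.sigma_A + 0.1

    def test_profile_must_end_without_analyte(self, params):
        with pytest.raises(ValueError):
            memory_experiment(params, AnalyteProfile.constant(2.0))


class TestDoseResponseAndHysteresis:
    def test_set_reset_curve_is_closed_form(self, params):
        A = np.array([0.0, 0.5, 1.5, 4.0])
        curve = dose_response(params, A, algorithms=("set_reset",))
        sigma = params.sigma_A * A + params.sigma_err
        np.testing.assert_allclose(curve.outputs["set_reset"],
                                   params.P * sigma / (params.rho + sigma),
                                   rtol=1e-5)

    def test_broadcast_threshold_at_zero(self, params):
        curve = dose_response(params, [0.0, 0.01, 1.0],
                              algorithms=("broadcast",))
        out = curve.outputs["broadcast"]
        assert out[0] == pytest.approx(0.0, abs=1.0)
        np.testing.assert_allclose(out[1:], params.P, rtol=1e-3)

    def test_hysteresis_between_saddle_points(self, params):
        sc = find_sigma_c(params).sigma_c
        sigmas = np.array([0.0, 0.8, 1.6, 2.4, sc + 0.2])
        up, down = hysteresis_sweep(params, sigmas)
        alpha_i, alpha_f = alpha_bounds(params)
        # ascending pass stays on the low branch until sigma_c is crossed;
        # the descending pass then remembers the committed state all the way
        assert np.all(up[:-1] < alpha_i * params.P)
        assert up[-1] > alpha_f * params.P
        assert np.all(down > alpha_f * params.P)
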