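"""Dual-uptake Michaelis-Menten model: forward solver, oracle and fitter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import serovolt as sv
from serovolt import mm
from serovolt.datatypes import ValidationError


class TestUptakeRate:
    @pytest.mark.parametrize("C, kwargs, expected", [
        (0.0, {}, 0.0),
        # half-saturation of Uptake 1 with Uptake 2 off
        (2.0, {"beta": 0.0}, 6.0),
        # control parameters at 2 nM: 12*2/4 + 780*2/172
        (2.0, {}, 12 * 2 / 4 + 780 * 2 / 172),
    ])
    def test_values(self, control_params, C, kwargs, expected):
        params = control_params.with_updates(**kwargs)
        assert mm.uptake_rate(C, params) == pytest.approx(expected, rel=1e-12)

    def test_negative_concentration_rejected(self, control_params):
        with pytest.raises(ValidationError):
            mm.uptake_rate(-1.0, control_params)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(c1=st.floats(0.0, 1e4), delta=st.floats(1e-6, 1e3))
    def test_monotone_and_bounded(self, c1, delta):
        params = sv.CONTROL_PARAMS
        lo = mm.uptake_rate(c1, params)
        hi = mm.uptake_rate(c1 + delta, params)
        cap = params.alpha * params.V_max1 + params.beta * params.V_max2
        assert hi > lo
        assert hi < cap


class TestSteadyState:
    def test_zero_release(self, control_params):
        assert mm.steady_state(0.0, control_params) == 0.0

    def test_single_uptake_closed_form(self, control_params):
        # C = R*Km1/(Vmax1 - R) with Km1=2, Vmax1=12, R=6 -> 2 nM
        params = control_params.with_updates(beta=0.0)
        assert mm.steady_state(6.0, params) == pytest.approx(2.0, rel=1e-12)

    def test_quadratic_root_satisfies_balance(self, control_params):
        for R in (1.0, 50.0, 400.0):
            c = mm.steady_state(R, control_params)
            assert mm.uptake_rate(c, control_params) == pytest.approx(R, rel=1e-10)

    def test_release_beyond_capacity_rejected(self, control_params):
        with pytest.raises(ValidationError):
            mm.steady_state(1000.0, control_params)

    def test_simulation_converges_to_steady_state(self, control_params):
        # constant release via an effectively instantaneous rise envelope
        params = control_params.with_updates(tau_on=1e-9, R_max=6.0, beta=0.0)
        proto = sv.StimulationProtocol(duration_s=60.0)
        trace = mm.simulate(params, proto, duration=60.0, stim_start=0.0)
        target = mm.steady_state(6.0, params)
        assert trace.concentration_nM[-1] == pytest.approx(target, rel=1e-3)


class TestSimulate:
    def test_no_release_stays_at_zero(self, control_params, protocol):
        params = control_params.with_updates(R_max=0.0, C0=0.0)
        trace = mm.simulate(params, protocol)
        assert np.all(trace.concentration_nM == 0.0)

    def test_ten_hz_grid_and_stim_annotation(self, control_trace):
        assert control_trace.dt_s == pytest.approx(0.1)
        assert control_trace.stim_start_s == 5.0
        assert control_trace.stim_end_s == 7.0

    def test_euler_first_order_convergence(self, control_params, protocol):
        """Halving dt roughly halves the sup-norm error vs a fine grid."""
        ref = mm.simulate(control_params, protocol, dt=0.00125)
        err = {}
        for dt in (0.01, 0.005):
            sol = mm.simulate(control_params, protocol, dt=dt)
            err[dt] = np.abs(sol.concentration_nM
                             - ref.concentration_nM).max()
        ratio = err[0.01] / err[0.005]
        assert 1.6 < ratio < 2.4

    def test_invalid_dt_rejected(self, control_params, protocol):
        with pytest.raises(ValidationError):
            mm.simulate(control_params, protocol, dt=0.0)

    def test_autoreceptor_term_damps_release(self, control_params, protocol):
        with_ar = control_params.with_updates(A_max=0.8, A_ec50=20.0)
        base = mm.simulate(control_params, protocol)
        damped = mm.simulate(with_ar, protocol)
        assert damped.concentration_nM.max() < base.concentration_nM.max()


class TestScenarioTraces:
    def test_caption_arithmetic(self, control_params, protocol):
        traces = mm.scenario_traces(control_params, protocol)
        p = {k: t.metadata["params"] for k, t in traces.items()}
        assert p["km2_x10"].K_m2 == 1700.0
        assert p["km2_x10"].K_m1 == control_params.K_m1
        assert p["km1_x10"].K_m1 == 20.0
        assert p["km1_x10_vmax1_x0.5"].K_m1 == 20.0
        assert p["km1_x10_vmax1_x0.5"].V_max1 == 6.0

    def test_every_scenario_slows_clearance(self, control_params, protocol,
                                            control_trace):
        from serovolt import fscv
        peak = fscv.detect_amp_max(control_trace)
        t_half_control = fscv.fit_half_life(control_trace,
                                            peak.t_peak_s).t_half_s
        for trace in mm.scenario_traces(control_params, protocol).values():
            pk = fscv.detect_amp_max(trace)
            t_half = fscv.fit_half_life(trace, pk.t_peak_s).t_half_s
            assert t_half > t_half_control


FREE_KM1 = frozenset(mm.FITTABLE_PARAMS) - {"K_m1"}
FREE_KM1_VMAX1 = frozenset(mm.FITTABLE_PARAMS) - {"K_m1", "V_max1"}


class TestFit:
    def test_fixed_point_at_truth(self, control_params, protocol,
                                  control_trace):
        res = mm.fit(control_trace, protocol, control_params,
                     frozen=FREE_KM1_VMAX1, n_starts=1, seed=0)
        assert res.rmse < 1e-6
        assert res.converged
        assert res.fitted.K_m1 == pytest.approx(control_params.K_m1, rel=1e-3)
        assert res.fitted.V_max1 == pytest.approx(control_params.V_max1,
                                                  rel=1e-3)

    def test_recovery_from_perturbed_init(self, control_params, protocol,
                                          control_trace):
        init = control_params.with_updates(K_m1=control_params.K_m1 * 1.3,
                                           V_max1=control_params.V_max1 * 0.7)
        res = mm.fit(control_trace, protocol, init, frozen=FREE_KM1_VMAX1,
                     n_starts=3, seed=1)
        assert res.fitted.K_m1 == pytest.approx(control_params.K_m1, rel=0.10)
        assert res.fitted.V_max1 == pytest.approx(control_params.V_max1,
                                                  rel=0.10)

    def test_recovers_tenfold_km1_ratio(self, control_params, protocol):
        truth = control_params.with_updates(K_m1=10 * control_params.K_m1)
        trace = mm.simulate(truth, protocol)
        res = mm.fit(trace, protocol, control_params, frozen=FREE_KM1,
                     n_starts=3, seed=2)
        ratio = res.fitted.K_m1 / control_params.K_m1
        assert ratio == pytest.approx(10.0, rel=0.15)

    def test_recovery_degrades_gracefully_with_noise(self, control_params,
                                                     protocol):
        from serovolt import synthetic
        truth = control_params.with_updates(K_m1=10 * control_params.K_m1)
        peak = mm.simulate(truth, protocol).concentration_nM.max()
        errors = []
        for frac in (0.0, 0.01, 0.05):
            trace = synthetic.simulate_evoked_trace(
                truth, protocol, noise_sd=frac * peak, seed=7)
            res = mm.fit(trace, protocol, control_params, frozen=FREE_KM1,
                         n_starts=2, seed=3)
            errors.append(abs(res.fitted.K_m1 / truth.K_m1 - 1.0))
        assert errors[0] < 0.01
        assert errors[-1] < 0.5  # noisy but not catastrophic

    def test_all_frozen_rejected(self, control_params, protocol,
                                 control_trace):
        with pytest.raises(ValidationError):
            mm.fit(control_trace, protocol, control_params,
                   frozen=mm.FITTABLE_PARAMS)

    def test_local_identifiability_of_free_set(self, control_params,
                                               protocol, control_trace):
        """Finite-difference Jacobian has full column rank on the free set."""
        free = ["R_max", "K_m1", "V_max1", "K_m2", "V_max2"]
        base = control_trace.concentration_nM
        cols = []
        for name in free:
            val = getattr(control_params, name)
            bumped = control_params.with_updates(**{name: val * 1.01})
            pert = mm.simulate(bumped, protocol).concentration_nM
            cols.append((pert - base) / (0.01 * val))
        J = np.column_stack(cols)
        assert np.linalg.matrix_rank(J) == len(free)


class TestParamRatios:
    def _fit_result(self, params, frozen=FREE_KM1_VMAX1):
        return mm.MMFitResult(fitted=params, rmse=0.0, iterations=0,
                              converged=True, frozen=frozenset(frozen))

    def test_identical_fits_ratio_one(self, control_params):
        a = self._fit_result(control_params)
        ratios = mm.param_ratios(a, a)
        assert all(r == 1.0 for r in ratios.values())

    def test_tenfold_and_half(self, control_params):
        post = self._fit_result(control_params.with_updates(K_m1=20.0,
                                                            V_max1=6.0))
        control = self._fit_result(control_params)
        ratios = mm.param_ratios(post, control)
        assert ratios["K_m1"] == pytest.approx(10.0)
        assert ratios["V_max1"] == pytest.approx(0.5)
        assert ratios["K_m2"] == 1.0  # frozen

    def test_mismatched_frozen_sets_rejected(self, control_params):
        a = self._fit_result(control_params, FREE_KM1)
        b = self._fit_result(control_params, FREE_KM1_VMAX1)
        with pytest.raises(ValidationError):
            mm.param_ratios(a, b)
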