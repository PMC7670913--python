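"""Unit and property tests for the core plasticity rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vplast as vp
from vplast.model import ModelState, integrate_protocol_loop


def zero_trace(duration=1000.0, dt=0.1):
    return vp.VoltageTrace(dt=dt, values=np.zeros(int(duration / dt) + 1))


class TestTypes:
    def test_invalid_params_rejected(self):
        good = dict(tau_x=5, tau_plus=6, tau_minus=15, theta_plus=10,
                    theta_0=5, A_LTP=1e-4, A_LTD=1e-4, b_theta=0, tau_theta=14)
        vp.PlasticityParams(**good)
        for bad in ({"tau_x": -1}, {"theta_plus": 4.0}, {"b_theta": -1},
                    {"A_LTP": float("nan")}, {"tau_theta": 0.0}):
            with pytest.raises(ValueError):
                vp.PlasticityParams(**{**good, **bad})

    def test_trace_rejects_nonfinite_sample_with_location(self):
        v = np.zeros(100)
        v[37] = np.nan
        with pytest.raises(ValueError, match="index 37"):
            vp.VoltageTrace(dt=0.1, values=v)

    def test_spike_train_must_increase(self):
        with pytest.raises(ValueError):
            vp.SpikeTrain(times=np.array([3.0, 2.0]))

    def test_trace_duration_convention(self):
        tr = zero_trace(10.0, 0.1)
        assert tr.n_samples == 101
        assert tr.duration == pytest.approx(10.0)


class TestStep:
    def test_spike_arrives_same_step(self, clamp_params):
        """A spike increments the glutamate trace in the step it arrives."""
        s = vp.step(ModelState(), 0.0, 1, 0.1, clamp_params)
        assert s.x_bar == pytest.approx(1.0)

    def test_negative_dt_rejected(self, clamp_params):
        with pytest.raises(ValueError):
            vp.step(ModelState(), 0.0, 0, -0.1, clamp_params)

    def test_nonfinite_voltage_rejected(self, clamp_params):
        with pytest.raises(ValueError):
            vp.step(ModelState(), float("inf"), 0, 0.1, clamp_params)

    def test_ltd_threshold_uses_previous_veto_state(self, clamp_params):
        """The veto variable updates after plasticity within a step, so LTD
        in the same step still sees the pre-step threshold."""
        p = clamp_params.replace(b_theta=1e6)
        state = ModelState(x_bar=0.0, u_bar_plus=20.0, u_bar_minus=20.0)
        s = vp.step(state, 20.0, 1, 0.1, p)
        # LTD accrued against theta_0 alone even though theta_var jumped
        expected_ltd = p.A_LTD * s.x_bar * (s.u_bar_minus - p.theta_0) * 0.1
        assert s.w_ltd == pytest.approx(expected_ltd, rel=1e-12)
        assert s.theta_var > 0


class TestIntegrateProtocol:
    def test_subthreshold_voltage_gives_exact_zero(self, clamp_params):
        spikes = vp.SpikeTrain(times=np.array([100.0, 200.0]))
        res = vp.integrate_protocol(zero_trace(), spikes, clamp_params)
        assert res.w_final == res.w_initial
        assert res.relative_change == 0.0

    def test_no_spikes_gives_exact_zero(self, clamp_params):
        tr = vp.VoltageTrace(dt=0.1, values=np.full(20001, 30.0))
        res = vp.integrate_protocol(tr, vp.SpikeTrain.empty(), clamp_params)
        assert res.w_final == res.w_initial

    def test_voltage_below_theta0_gives_exact_zero(self, clamp_params):
        tr = vp.VoltageTrace(dt=0.1, values=np.full(20001, clamp_params.theta_0 - 0.5))
        sp = vp.SpikeTrain(times=np.arange(100.0, 1900.0, 200.0))
        res = vp.integrate_protocol(tr, sp, clamp_params)
        assert res.w_final == res.w_initial

    def test_determinism(self, ca3_params, kernels):
        comps = vp.make_pairing_protocol(vp.ProtocolSpec(
            interval_ms=-10.0, repetitions=2, frequency_hz=1.0), kernels)
        tr, sp, _ = comps[0]
        a = vp.integrate_protocol(tr, sp, ca3_params)
        b = vp.integrate_protocol(tr, sp, ca3_params)
        assert a.w_final == b.w_final and a.w_ltp == b.w_ltp

    def test_decomposition_and_loop_equivalence(self, ca3_params, kernels):
        """w_final − w_init = w_ltp − w_ltd, and the vectorised integrator
        matches the scalar per-step reference."""
        comps = vp.make_pairing_protocol(vp.ProtocolSpec(
            interval_ms=-10.0, repetitions=3, frequency_hz=1.0,
            post_pattern=(3, 200.0)), kernels)
        tr, sp, _ = comps[0]
        fast = vp.integrate_protocol(tr, sp, ca3_params)
        slow = integrate_protocol_loop(tr, sp, ca3_params)
        assert fast.w_final - fast.w_initial == pytest.approx(
            fast.w_ltp - fast.w_ltd, abs=1e-15)
        assert fast.w_final == pytest.approx(slow.w_final, abs=1e-12)
        assert fast.w_ltp == pytest.approx(slow.w_ltp, abs=1e-12)

    def test_spike_outside_span_rejected(self, clamp_params):
        with pytest.raises(ValueError, match="5000"):
            vp.integrate_protocol(zero_trace(1000.0),
                                  vp.SpikeTrain(times=np.array([5000.0])),
                                  clamp_params)

    def test_spike_at_t0_belongs_to_first_step(self, clamp_params):
        tr = zero_trace(10.0)
        res = vp.integrate_protocol(tr, vp.SpikeTrain(times=np.array([0.0])),
                                    clamp_params, record_trajectory=True)
        assert res.trajectory.x_bar[1] == pytest.approx(1.0)

    def test_equilibrated_clamp_matches_closed_form(self, clamp_params):
        """Total LTP of one spike under supra-threshold clamp equals
        A_LTP·(u0 − θ₊)·τ_x once the filters have equilibrated."""
        p = clamp_params.replace(b_theta=0.0)
        u0 = p.theta_plus + 10.0
        warm = 10 * max(p.tau_plus, p.tau_minus)
        tr = vp.make_clamp_trace(u0, warm + 20 * p.tau_x)
        sp = vp.SpikeTrain(times=np.array([warm]))
        res = vp.integrate_protocol(tr, sp, p)
        expected = vp.analytic_single_spike_ltp(u0, p)
        assert expected == pytest.approx(5e-3)  # 1e-4 mV⁻¹ms⁻¹ · 10 mV · 5 ms
        assert res.w_ltp == pytest.approx(expected, rel=1e-3)

    def test_filter_dc_gain_and_step_response(self, clamp_params):
        u0 = 20.0
        tr = vp.make_clamp_trace(u0, 20 * clamp_params.tau_minus)
        res = vp.integrate_protocol(tr, vp.SpikeTrain.empty(), clamp_params,
                                    record_trajectory=True)
        traj = res.trajectory
        for tau, arr in ((clamp_params.tau_plus, traj.u_bar_plus),
                         (clamp_params.tau_minus, traj.u_bar_minus)):
            i_tau = int(round(tau / tr.dt))
            assert arr[i_tau] == pytest.approx(u0 * (1 - np.exp(-1)), rel=0.01)
            i_ss = int(round(10 * tau / tr.dt))
            assert abs(arr[i_ss] - u0) < 1e-4 * u0

    def test_ltp_monotone_in_voltage_without_veto(self, clamp_params, kernels):
        """Pointwise-larger voltage never decreases accumulated LTP (b_θ=0)."""
        p = clamp_params.replace(b_theta=0.0)
        comps = vp.make_pairing_protocol(vp.ProtocolSpec(
            interval_ms=10.0, repetitions=3, frequency_hz=5.0), kernels)
        tr, sp, _ = comps[0]
        lo = vp.integrate_protocol(tr, sp, p)
        hi = vp.integrate_protocol(
            vp.VoltageTrace(dt=tr.dt, values=tr.values + 2.0, t0=tr.t0), sp, p)
        assert hi.w_ltp >= lo.w_ltp


class TestVeto:
    def test_veto_reduces_ltd_never_ltp(self, clamp_params, random_protocols):
        """Across random protocols, raising b_θ never increases accumulated
        LTD and never changes accumulated LTP."""
        b_grid = [0.0, 1e3, 3e4, 2e5]
        checked_active = 0
        for tr, sp in random_protocols:
            prev_ltd = None
            ltps = []
            for b in b_grid:
                res = vp.integrate_protocol(tr, sp, clamp_params.replace(b_theta=b))
                if prev_ltd is not None:
                    assert res.w_ltd <= prev_ltd + 1e-15
                prev_ltd = res.w_ltd
                ltps.append(res.w_ltp)
            assert max(ltps) == pytest.approx(min(ltps), abs=1e-15)
            if ltps[0] > 0:
                checked_active += 1
        assert checked_active >= 5  # the bag must actually exercise LTP

    def test_theta_var_stays_nonnegative(self, clamp_params, random_protocols):
        tr, sp = random_protocols[1]
        res = vp.integrate_protocol(tr, sp, clamp_params, record_trajectory=True)
        assert np.all(res.trajectory.theta_var >= 0)


class TestTrialMixture:
    def test_single_component_matches_integrate(self, ca3_params, kernels):
        comps = vp.make_pairing_protocol(vp.ProtocolSpec(
            interval_ms=10.0, repetitions=1), kernels)
        tr, sp, _ = comps[0]
        direct = vp.integrate_protocol(tr, sp, ca3_params)
        mixed = vp.simulate_trial_mixture([(tr, sp, 1)], ca3_params)
        assert mixed.w_final == direct.w_final

    def test_mixture_is_linear_in_repetitions(self, ca3_params, kernels):
        comps = vp.make_pairing_protocol(vp.ProtocolSpec(
            interval_ms=10.0, repetitions=1, post_pattern=(3, 200.0)), kernels)
        tr, sp, _ = comps[0]
        tr2, sp2 = vp.make_square_pulse_protocol(25.0, 10.0, 5.0)
        d1 = vp.integrate_protocol(tr, sp, ca3_params)
        d2 = vp.integrate_protocol(tr2, sp2, ca3_params)
        mix = vp.simulate_trial_mixture([(tr, sp, 3), (tr2, sp2, 7)], ca3_params)
        expected = 3 * (d1.w_ltp - d1.w_ltd) + 7 * (d2.w_ltp - d2.w_ltd)
        assert mix.w_final - mix.w_initial == pytest.approx(expected, abs=1e-14)

    def test_supralinear_trials_set_the_sign(self, ca3_params):
        """When only supralinear trials cross threshold, the mixture outcome
        carries the sign of the supralinear contribution (60 pairings split
        40 linear / 20 supralinear)."""
        quiet = vp.KernelParams(epsp_amp=1.2, dspike_amp=25.0)
        comps = vp.make_pairing_protocol(vp.ProtocolSpec(
            interval_ms=10.0, repetitions=60, frequency_hz=0.1,
            post_pattern=(0, 200.0), per_trial=True,
            composition={"linear": 40 / 60, "supralinear": 20 / 60}),
            quiet)
        by_kind = {"linear": None, "supralinear": None}
        for i, (tr, sp, reps) in enumerate(comps):
            res = vp.integrate_protocol(tr, sp, ca3_params)
            key = "linear" if reps == 40 else "supralinear"
            by_kind[key] = res
        assert by_kind["linear"].relative_change == 0.0
        assert by_kind["supralinear"].relative_change != 0.0
        mix = vp.simulate_trial_mixture(
            [(c[0], c[1], c[2]) for c in comps], ca3_params)
        assert np.sign(mix.relative_change) == np.sign(
            by_kind["supralinear"].relative_change)

    def test_mismatched_dt_rejected(self, clamp_params):
        a = vp.make_clamp_trace(5.0, 100.0, dt=0.1)
        b = vp.make_clamp_trace(5.0, 100.0, dt=0.2)
        with pytest.raises(ValueError, match="dt"):
            vp.simulate_trial_mixture(
                [(a, vp.SpikeTrain.empty(), 1), (b, vp.SpikeTrain.empty(), 1)],
                clamp_params)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(u0=st.floats(0.0, 30.0), b=st.floats(0.0, 1e5),
       n_spikes=st.integers(0, 5))
def test_gating_and_decomposition_property(u0, b, n_spikes):
    """For any clamp level and veto strength: no spikes ⇒ no change,
    sub-θ₀ voltage ⇒ no change, and always w − w_init = w_ltp − w_ltd."""
    p = vp.PRESETS["clamp-demo-linear"].replace(b_theta=b)
    tr = vp.make_clamp_trace(u0, 500.0)
    sp = vp.SpikeTrain(times=50.0 + 60.0 * np.arange(n_spikes))
    res = vp.integrate_protocol(tr, sp, p)
    if n_spikes == 0 or u0 <= p.theta_0:
        assert res.w_final == res.w_initial
    assert res.w_final - res.w_initial == pytest.approx(
        res.w_ltp - res.w_ltd, abs=1e-15)
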