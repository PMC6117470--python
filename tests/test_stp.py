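"""Short-term plasticity model: closed forms, grid oracle, fitting."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synaptomap import stp
from synaptomap.stp import (FREE_ALL, FREE_KNOCKOUT, PRESETS, ScalingField,
                            SpikePattern, cohort_compare, epsp_peak_time,
                            epsp_trace, fit_stp, map_response, pattern,
                            stp_amplitudes, synapse_field,
                            theta_burst_indices)

CONTROL = PRESETS["control"]


def grid_simulation(times, p, dt=0.01):
    """Brute-force oracle: march the three history sums on a fine grid."""
    times = np.asarray(times, float)
    amps = []
    d_sum = f_sum = s_sum = 0.0
    kd = np.exp(-dt / p.tau_d0)
    kf = np.exp(-dt / p.tau_f0)
    ks = np.exp(-dt / p.tau_s0)
    t = 0.0
    next_i = 0
    n_steps = int(round((times[-1]) / dt)) + 1
    for step in range(n_steps + 1):
        t = step * dt
        while next_i < len(times) and abs(t - times[next_i]) < dt / 2:
            a_td = max(1.0 - d_sum, 0.0)
            a_tf = min(1.0 + f_sum + s_sum, p.cap)
            amps.append(a_tf * a_td)
            d_sum += p.A_d0
            f_sum += p.A_f0
            s_sum += p.A_s0
            next_i += 1
        d_sum *= kd
        f_sum *= kf
        s_sum *= ks
    return np.array(amps)


class TestAmplitudes:
    def test_single_spike_unit_amplitude(self):
        assert stp_amplitudes([0.0], CONTROL)[0] == 1.0

    def test_paired_pulse_closed_form(self):
        # control pair at IPI 25 ms, hand-derived closed form
        amps = stp_amplitudes([0.0, 25.0], CONTROL)
        expect = ((1 + 4.9 * np.exp(-25 / 13) + 0.458 * np.exp(-25 / 60))
                  * (1 - 0.25 * np.exp(-25 / 130)))
        assert amps[1] == pytest.approx(expect, abs=1e-9)
        assert expect == pytest.approx(1.602, abs=1e-3)

    def test_dense_train_saturates_cap_and_floor(self):
        times = np.arange(100, dtype=float)  # 100 spikes, 1 ms spacing
        amps, a_tf, a_td = stp_amplitudes(times, CONTROL, return_factors=True)
        assert a_tf.max() == pytest.approx(3.3)
        assert a_td.min() == 0.0
        assert amps[-1] == 0.0

    @pytest.mark.parametrize("preset", list(PRESETS))
    def test_matches_fine_grid_oracle(self, preset):
        p = PRESETS[preset]
        times = np.array([0.0, 25.0, 50.0, 75.0, 200.0, 225.0, 310.0])
        got = stp_amplitudes(times, p)
        want = grid_simulation(times, p)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_grid_oracle_on_random_trains(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            times = np.unique(np.round(
                np.sort(rng.uniform(0, 400, 12)), 2))
            got = stp_amplitudes(times, CONTROL)
            want = grid_simulation(times, CONTROL)
            np.testing.assert_allclose(got, want, atol=1e-6)

    def test_plasticity_off_identity(self):
        p = replace(CONTROL, A_d0=0.0, A_f0=0.0, A_s0=0.0)
        times = np.sort(np.random.default_rng(1).uniform(0, 500, 20))
        np.testing.assert_allclose(stp_amplitudes(times, p), 1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.5, 500.0), min_size=1, max_size=30,
                    unique=True))
    def test_factors_bounded_for_any_pattern(self, raw_times):
        times = np.sort(np.asarray(raw_times))
        _, a_tf, a_td = stp_amplitudes(times, CONTROL, return_factors=True)
        assert (a_tf <= 3.3 + 1e-12).all()
        assert (a_tf >= 1.0).all()
        assert (a_td >= 0.0).all()
        assert (a_tf * a_td >= 0.0).all()

    def test_non_increasing_times_fail(self):
        with pytest.raises(ValueError):
            stp_amplitudes([10.0, 5.0], CONTROL)


class TestTrace:
    def test_analytic_peak_time(self):
        assert epsp_peak_time() == pytest.approx(0.930, abs=1e-3)

    def test_zero_before_first_spike(self):
        t, v, _ = epsp_trace([100.0], [1.0], dt=1.0, t_max=200.0)
        assert np.allclose(v[t < 100.0], 0.0)

    def test_linearity_in_amplitudes(self):
        times = [0.0, 30.0]
        _, v1, p1 = epsp_trace(times, [1.0, 1.5])
        _, v2, p2 = epsp_trace(times, [2.0, 3.0])
        np.testing.assert_allclose(v2, 2 * v1)
        np.testing.assert_allclose(p2, 2 * p1)

    def test_peak_value_matches_dense_grid(self):
        t, v, peaks = epsp_trace([0.0], [1.0], dt=0.0005, t_max=10.0)
        assert v.max() == pytest.approx(peaks[0], rel=1e-5)
        assert t[np.argmax(v)] == pytest.approx(epsp_peak_time(), abs=1e-3)

    def test_bad_dt_fails(self):
        with pytest.raises(ValueError):
            epsp_trace([0.0], [1.0], dt=0.0)


class TestPatterns:
    def test_mixed_pattern_exact_times(self):
        np.testing.assert_allclose(pattern("mixed").times_ms,
                                   [25, 50, 120, 145, 205, 270, 310])

    def test_theta_all_lags_200(self):
        p = pattern("theta", 8)
        np.testing.assert_allclose(np.diff(p.times_ms), 200.0)

    def test_gamma_all_lags_25(self):
        np.testing.assert_allclose(np.diff(pattern("gamma", 8).times_ms), 25.0)

    def test_theta_burst_two_bursts_of_four(self):
        p = pattern("theta_burst", 8)
        lags = np.diff(p.times_ms)
        np.testing.assert_allclose(lags[[0, 1, 2, 4, 5, 6]], 25.0)
        assert lags[3] == pytest.approx(125.0)       # gap convention
        assert p.times_ms[4] == pytest.approx(200.0)  # 5 Hz burst onsets

    def test_theta_burst_onset_convention(self):
        p = pattern("theta_burst", 8, ibi_mode="onset")
        assert p.times_ms[4] == pytest.approx(125.0)

    def test_gamma_doublets(self):
        p = pattern("gamma_doublets", 4)
        np.testing.assert_allclose(np.diff(p.times_ms)[[0, 2]], 13.0)

    def test_unknown_pattern_fails(self):
        with pytest.raises(ValueError):
            pattern("ripple")

    def test_invalid_spike_times_fail(self):
        with pytest.raises(ValueError):
            SpikePattern("bad", np.array([1.0, 1.0]))


class TestField:
    def test_constant_profiles_reproduce_base(self):
        fld = synapse_field([1.0, 1.0], [1.0, 1.0], [1.0, 1.0], [1.0, 1.0],
                            n_tangential=5)
        for i in range(len(fld)):
            assert fld.params_at(i) == CONTROL

    def test_default_1d_grid_has_101_synapses(self):
        prof = np.linspace(0.2, 1.0, 10)
        fld = synapse_field(prof, prof, prof[::-1], prof)
        assert len(fld) == 101

    def test_default_2d_grid_has_121_synapses(self):
        prof = np.linspace(0.2, 1.0, 10)
        fld = synapse_field(prof, prof, prof[::-1], prof,
                            n_tangential=11, n_radial=11)
        assert len(fld) == 121

    def test_spline_interpolates_sample_points(self):
        prof = np.array([0.2, 0.8, 0.4])
        fld = synapse_field(prof, [1.0], [1.0], [1.0], n_tangential=5)
        np.testing.assert_allclose(fld.S_Ad[[0, 2, 4]], prof, atol=1e-12)

    def test_floor_clamp(self):
        fld = synapse_field([0.0, 0.0], [1.0], [1.0], [1.0], n_tangential=3)
        assert (fld.S_Ad >= 0.05).all()

    def test_out_of_range_profile_fails(self):
        with pytest.raises(ValueError):
            synapse_field([0.0, 1.5], [1.0], [1.0], [1.0])


class TestResponseMap:
    def test_uniform_field_all_normalized_one(self):
        fld = synapse_field([1.0, 1.0], [1.0], [1.0], [1.0], n_tangential=7)
        rm = map_response(fld, pattern("theta_burst", 8))
        np.testing.assert_allclose(rm.normalized, 1.0)

    def test_monotone_saf_gradient_gives_monotone_response(self):
        # facilitation amplitude rises along the axis, depression constant
        saf = np.linspace(0.1, 1.0, 11)
        fld = synapse_field([1.0, 1.0], [1.0], saf, [1.0], n_tangential=11)
        rm = map_response(fld, pattern("theta_burst", 8))
        assert (np.diff(rm.responses) > 0).all()

    def test_normalized_max_exactly_one(self):
        prof = np.linspace(0.3, 1.0, 6)
        fld = synapse_field(prof, prof, prof[::-1], prof, n_tangential=21)
        rm = map_response(fld, pattern("gamma", 8))
        assert rm.normalized.max() == 1.0
        assert rm.normalized.min() >= 0.0

    def test_shared_normalization_group(self):
        fld = synapse_field([0.5, 1.0], [1.0], [0.5, 1.0], [1.0],
                            n_tangential=9)
        r1 = map_response(fld, pattern("theta_burst", 8))
        r2 = map_response(fld, pattern("theta", 8),
                          shared_max=r1.responses.max())
        assert r2.normalized.max() < 1.0  # theta facilitates less

    def test_max_min_ratio(self):
        rm_attrs = ScalingField(np.arange(2), np.zeros(2), np.ones(2),
                                np.ones(2), np.ones(2), np.ones(2))
        rm = map_response(rm_attrs, pattern("theta", 2))
        assert rm.max_min_ratio == pytest.approx(1.0)


class TestFitting:
    def test_burst_indices_shape(self):
        idx = theta_burst_indices()
        assert len(idx) == 16
        np.testing.assert_array_equal(idx[:4], [0, 1, 2, 3])
        np.testing.assert_array_equal(idx[-4:], [36, 37, 38, 39])

    @pytest.mark.parametrize("preset", list(PRESETS))
    def test_self_consistency_zero_residual(self, preset):
        base = PRESETS[preset]
        pat = pattern("theta_burst", 40)
        idx = theta_burst_indices()
        target = stp_amplitudes(pat.times_ms, base)[idx]
        init = replace(base, **{k: getattr(base, k) * 1.5 for k in FREE_ALL})
        fitted, sse, ok = fit_stp(target, pat, init=init, base=base,
                                  select_idx=idx)
        assert sse < 1e-10
        refit = stp_amplitudes(pat.times_ms, fitted)[idx]
        np.testing.assert_allclose(refit, target, atol=1e-6)

    def test_control_parameter_recovery_within_one_percent(self):
        base = CONTROL
        pat = pattern("theta_burst", 40)
        idx = theta_burst_indices()
        target = stp_amplitudes(pat.times_ms, base)[idx]
        init = replace(base, **{k: getattr(base, k) * 1.5 for k in FREE_ALL})
        fitted, _, _ = fit_stp(target, pat, init=init, base=base,
                               select_idx=idx)
        assert fitted.A_d0 == pytest.approx(0.25, rel=0.01)
        assert fitted.A_f0 == pytest.approx(4.9, rel=0.01)

    def test_knockout_mode_frees_exactly_three(self):
        base = PRESETS["psd95"]
        pat = pattern("theta_burst", 8)
        target = stp_amplitudes(pat.times_ms, base)
        init = replace(CONTROL)
        fitted, sse, _ = fit_stp(target, pat, free=FREE_KNOCKOUT, init=init,
                                 base=CONTROL)
        assert len(FREE_KNOCKOUT) == 3
        # frozen parameters stay at the control base values
        assert fitted.tau_f0 == CONTROL.tau_f0
        assert fitted.A_s0 == CONTROL.A_s0
        assert fitted.tau_s0 == CONTROL.tau_s0
        assert sse < 1e-8

    def test_misaligned_target_fails(self):
        with pytest.raises(ValueError):
            fit_stp([1.0, 1.0], pattern("theta", 8))


class TestCohorts:
    def test_identical_cohorts(self):
        r = np.array([1.0, 2.0, 3.0, 4.0])
        rep = cohort_compare(r, r)
        assert rep["ks_statistic"] == 0.0
        assert rep["ks_p"] == pytest.approx(1.0)
        assert not rep["significant"]

    def test_shifted_cohorts_significant(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 121)
        b = rng.normal(3, 1, 121)
        rep = cohort_compare(a, b)
        assert rep["ks_p"] < 0.05 and rep["t_p"] < 0.05
        assert rep["significant"]

    def test_max_min_ratio_reported(self):
        rep = cohort_compare([2.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert rep["ratio_a"] == pytest.approx(2.0)

    def test_too_few_synapses_fail(self):
        with pytest.raises(ValueError):
            cohort_compare([1.0, 2.0], [1.0, 2.0, 3.0])
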