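"""Spike detection, AP metrics, firing classification, passive properties,
subtraction protocols and curve fits."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

import leakfire as lf
from leakfire.ephys_features import (
    NotExcitableError,
    SpikeTrain,
    ap_waveform_features,
    activation_tau_fit,
    boltzmann_activation_fit,
    build_vi_iv,
    capacitance_from_transient,
    classify_firing,
    detect_spikes,
    difference_current_reversal,
    fit_membrane_tau,
    input_resistance,
    junction_correct,
    nernst_potential,
    p_over_minus4_subtract,
    rheobase_and_latency,
    sag_amplitude,
)
from leakfire.protocol_engine import StepProtocol, Trace


def make_trace(t, v, proto=None, unit="mV"):
    return Trace(np.asarray(t, float), np.asarray(v, float), unit, protocol=proto)


def spike_bump(t, t0, sigma=0.5, base=-70.0, peak=30.0):
    return base + (peak - base) * np.exp(-0.5 * ((t - t0) / sigma) ** 2)


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        t = np.arange(0.0, 100.0, 0.02)
        assert len(detect_spikes(make_trace(t, np.full_like(t, -70.0)))) == 0

    def test_constructed_spikes_found_at_their_times(self):
        t = np.arange(0.0, 100.0, 0.02)
        v = np.full_like(t, -70.0)
        for t0 in (20.0, 45.0, 80.0):
            v = np.maximum(v, spike_bump(t, t0))
        st = detect_spikes(make_trace(t, v))
        assert len(st) == 3
        np.testing.assert_allclose(st.times_ms, [20.0, 45.0, 80.0], atol=0.02)
        np.testing.assert_allclose(st.peaks_mV, 30.0, atol=0.01)

    def test_refractory_merging(self):
        # two peaks 1 ms apart count once (the larger wins)
        t = np.arange(0.0, 50.0, 0.02)
        v = np.maximum(spike_bump(t, 20.0, peak=20.0), spike_bump(t, 21.0, peak=28.0))
        st = detect_spikes(make_trace(t, v))
        assert len(st) == 1 and st.peaks_mV[0] == pytest.approx(28.0, abs=0.1)

    def test_current_trace_rejected(self):
        t = np.arange(0.0, 10.0, 0.1)
        with pytest.raises(ValueError):
            detect_spikes(make_trace(t, np.zeros_like(t), unit="pA"))


class TestClassifyFiring:
    PROTO = StepProtocol(baseline_ms=100.0, step_ms=500.0, post_ms=50.0)

    def make_train(self, times):
        times = np.asarray(times, float)
        return SpikeTrain(times, np.full_like(times, 20.0))

    def test_silent_and_phasic(self):
        assert classify_firing(self.make_train([]), self.PROTO).label == "silent"
        assert classify_firing(self.make_train([150.0]), self.PROTO).label == "phasic"

    def test_early_terminating_train_is_transient(self):
        fc = classify_firing(self.make_train([110.0, 130.0, 150.0]), self.PROTO)
        assert fc.label == "transient" and fc.count == 3

    def test_sustained_train_is_tonic(self):
        fc = classify_firing(self.make_train(np.arange(110.0, 600.0, 25.0)), self.PROTO)
        assert fc.label == "tonic"

    def test_invariant_to_resampling_and_small_noise(self, base_params):
        # model trace at the transient point keeps its class after 2x
        # oversampling and after 0.2 mV RMS additive noise
        proto = StepProtocol()
        tr = lf.simulate_current_clamp(base_params.with_leak_nS(5.4), proto)
        base = classify_firing(detect_spikes(tr), proto).label
        assert base == "transient"
        half = Trace(tr.t_ms[::2], tr.values[::2], "mV", protocol=proto)
        assert classify_firing(detect_spikes(half), proto).label == base
        rng = np.random.default_rng(7)
        noisy = Trace(tr.t_ms, tr.values + rng.normal(0, 0.2, tr.values.size),
                      "mV", protocol=proto)
        assert classify_firing(detect_spikes(noisy), proto).label == base


class TestApWaveform:
    def test_gaussian_bump_half_width(self):
        # FWHM of a Gaussian riding from its own threshold: 2.355 sigma
        sigma = 1.2
        proto = StepProtocol(baseline_ms=100.0, step_ms=100.0, post_ms=50.0)
        t = proto.times()
        v = -70.0 + 100.0 * np.exp(-0.5 * ((t - 150.0) / sigma) ** 2)
        tr = make_trace(t, v, proto)
        st = detect_spikes(tr)
        feats = ap_waveform_features(tr, st)
        hw = feats["half_width_ms"].iloc[0]
        # threshold sits near the baseline for a tall narrow bump, so the
        # half-amplitude level is close to the true FWHM level
        assert hw == pytest.approx(2.355 * sigma, rel=0.08)

    def test_model_trace_threshold_bracket(self, base_params):
        # noiseless baseline: SD = 0, the dV/dt floor engages; the detected
        # threshold falls between the upstroke foot (last local minimum of
        # dV/dt before the maximal rate of rise — the curvature oracle) and
        # the half-height of the AP
        tr = lf.simulate_current_clamp(base_params.with_leak_nS(5.6), StepProtocol())
        st = detect_spikes(tr)
        feats = ap_waveform_features(tr, st)
        thr = feats["threshold_mV"].iloc[0]
        dvdt = np.gradient(tr.values, tr.t_ms)
        j_peak = int(np.argmin(np.abs(tr.t_ms - st.times_ms[0])))
        j_up = int(np.argmax(dvdt[:j_peak + 1]))
        j = j_up
        while j > 0 and dvdt[j - 1] <= dvdt[j]:
            j -= 1
        v_foot = tr.values[j]
        assert v_foot - 0.5 <= thr < 0.5 * (v_foot + st.peaks_mV[0])
        assert -65.0 < thr < -20.0  # physiological sanity window
        assert feats["threshold_t_ms"].iloc[0] < st.times_ms[0]

    def test_requires_baseline(self, base_params):
        proto = StepProtocol(baseline_ms=10.0, step_ms=200.0, post_ms=10.0)
        tr = lf.simulate_current_clamp(base_params.with_leak_nS(5.6), proto)
        with pytest.raises(ValueError):
            ap_waveform_features(tr, detect_spikes(tr))


class TestRheobase:
    def test_passive_cell_not_excitable(self, passive_params):
        with pytest.raises(NotExcitableError):
            rheobase_and_latency(passive_params, step_ms=100.0, i_max_pA=400.0)

    def test_model_rheobase_below_probe_current(self, base_params):
        # at the phasic edge the 120 pA probe is suprathreshold
        rheo, latency = rheobase_and_latency(base_params.with_leak_nS(5.6),
                                             step_ms=300.0, resolution_pA=5.0)
        assert rheo < 120.0
        assert 0.0 < latency < 300.0

    def test_bisection_resolution_contract(self, base_params):
        # halving the resolution can only lower the reported rheobase, and
        # by no more than the coarser resolution
        p = base_params.with_leak_nS(5.6)
        r10, _ = rheobase_and_latency(p, step_ms=200.0, resolution_pA=10.0,
                                      i_max_pA=200.0)
        r5, _ = rheobase_and_latency(p, step_ms=200.0, resolution_pA=5.0,
                                     i_max_pA=200.0)
        assert r5 <= r10 + 1e-9
        assert r10 - r5 <= 10.0 + 1e-9


class TestViIv:
    @staticmethod
    def ohmic_family(r_MOhm=100.0, amps=(-50.0, -25.0), rest=-70.0):
        traces = []
        for a in amps:
            proto = StepProtocol(baseline_ms=50.0, step_ms=300.0, amplitude=a,
                                 post_ms=0.0, dt_ms=0.5)
            t = proto.times()
            v = np.full_like(t, rest)
            in_step = (t >= 50.0) & (t < 350.0)
            v[in_step] += a * r_MOhm * 1e-3  # pA * MOhm = uV -> mV via 1e-3
            traces.append(make_trace(t, v, proto))
        return traces

    def test_passive_points_exact(self):
        vi = build_vi_iv(self.ohmic_family())
        assert vi.steady.tolist() == pytest.approx([-75.0, -72.5])

    def test_window_longer_than_step_rejected(self):
        with pytest.raises(ValueError):
            build_vi_iv(self.ohmic_family(), window_ms=400.0)

    def test_input_resistance_recovers_ohmic_cell(self):
        vi = build_vi_iv(self.ohmic_family(r_MOhm=100.0))
        assert input_resistance(vi) == pytest.approx(100.0, rel=1e-9)

    def test_points_above_minus60_rejected(self):
        vi = build_vi_iv(self.ohmic_family(rest=-50.0, amps=(25.0, 50.0)))
        with pytest.raises(ValueError):
            input_resistance(vi)

    def test_recovery_on_simulated_family(self, passive_params):
        # engine-simulated hyperpolarizing family recovers 1/g within 0.5%
        p = passive_params.with_leak_nS(8.0)
        traces = [lf.simulate_current_clamp(
            p, StepProtocol(baseline_ms=50.0, step_ms=300.0, amplitude=a, post_ms=0.0))
            for a in (-100.0, -50.0, -25.0)]
        vi = build_vi_iv(traces)
        assert input_resistance(vi) == pytest.approx(125.0, rel=5e-3)


class TestMembraneTau:
    def test_pure_exponential_exact(self):
        t = np.arange(0.0, 100.0, 0.1)
        v = -70.0 + 10.0 * np.exp(-t / 20.0)
        tau, rms = fit_membrane_tau(make_trace(t, v), 0.0, 100.0)
        assert tau == pytest.approx(20.0, rel=1e-6)
        assert rms < 1e-9

    @pytest.mark.parametrize("seed", range(10))
    def test_noisy_recovery_within_5_percent(self, seed):
        # the published phasic-cell mean (13.9 ms) plus 0.3 mV noise
        rng = np.random.default_rng(seed)
        t = np.arange(0.0, 120.0, 0.1)
        v = -70.0 - 12.0 * np.exp(-t / 13.9) + rng.normal(0, 0.3, t.size)
        tau, _ = fit_membrane_tau(make_trace(t, v), 0.0, 120.0)
        assert abs(tau - 13.9) / 13.9 < 0.05

    def test_biexponential_flags_poor_fit(self):
        t = np.arange(0.0, 200.0, 0.1)
        v_bi = -70.0 + 8.0 * np.exp(-t / 3.0) + 8.0 * np.exp(-t / 60.0)
        v_mono = -70.0 + 16.0 * np.exp(-t / 20.0)
        _, rms_bi = fit_membrane_tau(make_trace(t, v_bi), 0.0, 200.0)
        _, rms_mono = fit_membrane_tau(make_trace(t, v_mono), 0.0, 200.0)
        assert rms_bi > 100.0 * max(rms_mono, 1e-12)


class TestSag:
    @staticmethod
    def hyper_proto():
        return StepProtocol(baseline_ms=100.0, step_ms=500.0, amplitude=-50.0,
                            post_ms=100.0, dt_ms=0.1)

    def test_passive_response_has_no_sag(self, passive_params):
        tr = lf.simulate_current_clamp(passive_params.with_leak_nS(3.6),
                                       self.hyper_proto())
        assert abs(sag_amplitude(tr)) < 0.1

    def test_constructed_relaxation_recovered(self):
        # relaxation begins once the (idealized) passive transient settles
        proto = self.hyper_proto()
        t = proto.times()
        v = np.full_like(t, -70.0)
        in_step = (t >= proto.onset_ms) & (t < proto.offset_ms)
        ts = np.maximum(t[in_step] - proto.onset_ms - 5.0, 0.0)
        v[in_step] = -100.0 + 4.5 * (1.0 - np.exp(-ts / 40.0))
        assert sag_amplitude(make_trace(t, v, proto)) == pytest.approx(4.5, abs=0.05)

    def test_noise_only_below_three_sigma(self):
        proto = self.hyper_proto()
        rng = np.random.default_rng(11)
        t = proto.times()
        v = np.full_like(t, -90.0) + rng.normal(0, 0.2, t.size)
        v[t < proto.onset_ms] = -70.0
        assert abs(sag_amplitude(make_trace(t, v, proto))) < 3 * 0.2

    def test_depolarizing_step_rejected(self, passive_params):
        tr = lf.simulate_current_clamp(passive_params,
                                       StepProtocol(amplitude=50.0))
        with pytest.raises(ValueError):
            sag_amplitude(tr)


class TestCapacitance:
    @staticmethod
    def clamp_cell(passive_params, c_pF=40.0, g_nS=0.1):
        p = dataclasses.replace(passive_params, area=c_pF * 1e-6)
        return p.with_leak_nS(g_nS)

    def test_charge_equals_C_times_dV(self, passive_params):
        p = self.clamp_cell(passive_params)
        proto = StepProtocol(baseline_ms=20.0, step_ms=80.0, holding=-70.0,
                             amplitude=10.0, post_ms=20.0, dt_ms=0.01)
        tr = lf.simulate_voltage_clamp(p, proto, series_resistance_MOhm=10.0)
        assert capacitance_from_transient(tr, 10.0) == pytest.approx(40.0, rel=0.01)

    def test_independent_of_series_resistance(self, passive_params):
        p = self.clamp_cell(passive_params)
        proto = StepProtocol(baseline_ms=20.0, step_ms=80.0, holding=-70.0,
                             amplitude=10.0, post_ms=20.0, dt_ms=0.01)
        estimates = [capacitance_from_transient(
            lf.simulate_voltage_clamp(p, proto, series_resistance_MOhm=rs), 10.0)
            for rs in (5.0, 10.0, 20.0)]
        assert max(estimates) / min(estimates) < 1.01

    def test_zero_dV_rejected(self, passive_params):
        p = self.clamp_cell(passive_params)
        proto = StepProtocol(baseline_ms=20.0, step_ms=80.0, holding=-70.0,
                             amplitude=10.0, post_ms=20.0, dt_ms=0.01)
        tr = lf.simulate_voltage_clamp(p, proto, series_resistance_MOhm=10.0)
        with pytest.raises(ValueError):
            capacitance_from_transient(tr, 0.0)


class TestPOverMinus4:
    @staticmethod
    def vc_pair(params, main_amp=-60.0):
        main_proto = StepProtocol(baseline_ms=50.0, step_ms=200.0, holding=-50.0,
                                  amplitude=main_amp, post_ms=50.0, dt_ms=0.1)
        sub_proto = dataclasses.replace(main_proto, amplitude=-main_amp / 4.0)
        main = lf.simulate_voltage_clamp(params, main_proto)
        subs = [lf.simulate_voltage_clamp(params, sub_proto) for _ in range(4)]
        return main, subs

    def test_ohmic_cell_cancels_to_zero(self, passive_params):
        main, subs = self.vc_pair(passive_params.with_leak_nS(8.0))
        out = p_over_minus4_subtract(main, subs)
        assert np.max(np.abs(out.values)) < 1e-9 * np.max(np.abs(main.values))

    def test_voltage_gated_current_survives(self, base_params):
        # leak + Kdr cell: the subtraction leaves the Kdr current alone
        p = dataclasses.replace(base_params, gNa=0.0)
        main_proto = StepProtocol(baseline_ms=50.0, step_ms=400.0, holding=-70.0,
                                  amplitude=110.0, post_ms=50.0, dt_ms=0.1)
        sub_proto = dataclasses.replace(main_proto, amplitude=-110.0 / 4.0)
        main = lf.simulate_voltage_clamp(p, main_proto)
        subs = [lf.simulate_voltage_clamp(p, sub_proto) for _ in range(4)]
        out = p_over_minus4_subtract(main, subs)
        kdr_only = lf.simulate_voltage_clamp(
            dataclasses.replace(p, gL=0.0), main_proto)
        ref = kdr_only.values - kdr_only.values[kdr_only.t_ms < 50.0].mean()
        sel = main.t_ms > 100.0  # past the gating transient
        peak = np.max(np.abs(ref[sel]))
        assert np.max(np.abs(out.values[sel] - ref[sel])) < 0.01 * peak

    def test_wrong_subpulse_count_rejected(self, passive_params):
        main, subs = self.vc_pair(passive_params)
        with pytest.raises(ValueError):
            p_over_minus4_subtract(main, subs[:3])

    def test_wrong_subpulse_amplitude_rejected(self, passive_params):
        main, _ = self.vc_pair(passive_params)
        bad_subs = [main] * 4
        with pytest.raises(ValueError):
            p_over_minus4_subtract(main, bad_subs)


class TestBoltzmannFit:
    def test_noiseless_exact_recovery(self):
        V = np.linspace(-50.0, 70.0, 8)
        G = 1.0 / (1.0 + np.exp((8.4 - V) / 18.5))
        fit = boltzmann_activation_fit(V, G)
        assert fit.V_half_mV == pytest.approx(8.4, abs=1e-6)
        assert fit.slope_k_mV == pytest.approx(18.5, abs=1e-6)

    def test_noisy_median_recovery(self):
        rng = np.random.default_rng(123)
        errs = []
        for _ in range(40):
            V, G = lf.generate_activation_points(rng)
            errs.append(abs(boltzmann_activation_fit(V, G).V_half_mV - 8.4))
        assert np.median(errs) < 1.5

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError):
            boltzmann_activation_fit(np.linspace(-50, 70, 8), np.ones(8))
        with pytest.raises(ValueError):
            boltzmann_activation_fit(np.array([0.0, 10.0]), np.array([0.2, 0.8]))

    def test_activation_tau_near_gate_constant(self, base_params):
        # Kdr current at +30 mV: a single-exponential fit to the a^2 rise
        # lands within 15% of the underlying 3.2 ms gate constant
        p = dataclasses.replace(base_params, gNa=0.0, gL=0.0)
        proto = StepProtocol(baseline_ms=20.0, step_ms=100.0, holding=-70.0,
                             amplitude=100.0, post_ms=0.0, dt_ms=0.05)
        tr = lf.simulate_voltage_clamp(p, proto)
        tau, _ = activation_tau_fit(tr, fit_span_ms=30.0)
        assert abs(tau - 3.2) / 3.2 < 0.15


class TestDifferenceReversal:
    def test_synthetic_ohmic_recovery(self):
        rng = np.random.default_rng(5)
        V = np.array([-110.0, -90.0, -70.0, -50.0])
        base = 2.0 * (V + 77.0)
        diff = 5.9 * (V + 98.6)
        ctl = pd.DataFrame({"command": V, "steady": base + diff
                            + rng.normal(0, np.abs(diff) * 0.01)})
        blk = pd.DataFrame({"command": V, "steady": base})
        fit = difference_current_reversal(ctl, blk)
        assert fit.g_nS == pytest.approx(5.9, abs=0.2)
        assert fit.E_rev_mV == pytest.approx(-98.6, abs=2.0)
        assert fit.r_squared > 0.99

    def test_identical_ivs_rejected(self):
        iv = pd.DataFrame({"command": [-100.0, -60.0], "steady": [1.0, 2.0]})
        with pytest.raises(ValueError):
            difference_current_reversal(iv, iv.copy())


class TestNernstAndJunction:
    def test_printed_solutions_give_minus_105(self):
        # 2.5 mM K outside, 150 mM inside (130 gluconate + 20 Cl), 25 C
        assert nernst_potential(2.5, 150.0, 25.0) == pytest.approx(-105.2, abs=0.05)

    def test_concentration_validation(self):
        with pytest.raises(ValueError):
            nernst_potential(0.0, 150.0)

    def test_junction_shift_and_idempotence(self):
        t = np.arange(0.0, 10.0, 0.1)
        tr = make_trace(t, np.full_like(t, -60.0))
        corr = junction_correct(tr, 10.0)
        assert corr.values[0] == pytest.approx(-70.0)
        with pytest.warns(UserWarning):
            again = junction_correct(corr, 10.0)
        assert np.array_equal(again.values, corr.values)

    def test_zero_ljp_is_identity(self):
        t = np.arange(0.0, 10.0, 0.1)
        tr = make_trace(t, np.full_like(t, -60.0))
        assert np.array_equal(junction_correct(tr, 0.0).values, tr.values)
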