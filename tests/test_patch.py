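import numpy as np
import pytest
from conftest import brute_force_spikes

import slicephys as sp
from slicephys.core import ValidationError


def _ramp_sweep(slope_mv_per_ms, rate=25_000.0, dur=0.3):
    t = np.arange(0, dur, 1 / rate)
    return sp.TimeSeries(-70.0 + slope_mv_per_ms * t * 1e3, rate=rate, units="mV")


def _piecewise_spike(rate=25_000.0):
    """Slope jumps from 2 to 50 mV/ms at t = 100 ms, peak +30 mV later."""
    t = np.arange(0, 0.2, 1 / rate)
    v = np.where(t < 0.1, -70.0 + 2e3 * (t - 0.1), -70.0 + 50e3 * (t - 0.1))
    v = np.minimum(v, -70.0 + 40.0)  # clip into a flat 40 mV peak
    v[t > 0.105] = -72.0  # drop after the peak
    return sp.TimeSeries(v, rate=rate, units="mV")


class TestDetectSpikes:
    def test_subcriterion_ramp_has_no_spikes(self):
        assert sp.detect_spikes(_ramp_sweep(4.0)).n == 0

    def test_constructed_slope_jump_onset_timing(self):
        sw = _piecewise_spike()
        tr = sp.detect_spikes(sw)
        assert tr.n == 1
        assert tr.times[0] == pytest.approx(0.100, abs=1.5 / sw.rate)

    def test_matches_brute_force_derivative_scan(self, noiseless_cell):
        cfg, family, _ = noiseless_cell
        for amp in (140.0, 300.0, 600.0):
            sw = family.sweep_for(amp)
            got = sp.detect_spikes(sw).times
            want = brute_force_spikes(sw.samples, sw.rate)
            assert np.allclose(got, want, atol=1e-9)

    def test_generator_spike_times_recovered(self, noiseless_cell):
        _, family, truth = noiseless_cell
        for s in truth["per_sweep"]:
            if 0 < s["n_spikes"]:
                tr = sp.detect_spikes(family.sweep_for(s["amplitude"]))
                assert tr.n == s["n_spikes"]
                assert np.max(np.abs(tr.times - s["spike_onsets"])) < 0.2e-3


class TestApFeatures:
    def test_recovers_planted_template_features(self, noiseless_cell):
        _, family, truth = noiseless_cell
        amp = truth["adaptation_current"] if "adaptation_current" in truth else 150.0
        sweeps = [s for s in truth["per_sweep"]
                  if s["n_spikes"] >= 2 and s["isis"].min() > 0.09]
        s = sweeps[0]
        sw = family.sweep_for(s["amplitude"])
        tr = sp.detect_spikes(sw)
        ap = sp.ap_features(sw, tr.times[0], tr.times[1])
        gt = truth["ap"]
        assert ap.threshold_v == pytest.approx(gt.threshold_v, abs=0.2)
        assert ap.amplitude == pytest.approx(gt.amplitude, rel=0.05)
        assert ap.rise_10_90 == pytest.approx(gt.rise_10_90, rel=0.05)
        assert ap.half_width == pytest.approx(gt.half_width, rel=0.05)
        assert ap.fahp == pytest.approx(gt.fahp, abs=0.2)
        assert ap.mahp == pytest.approx(gt.mahp, abs=0.2)
        assert ap.time_to_mahp == pytest.approx(gt.time_to_mahp, rel=0.05)
        assert ap.adp == pytest.approx(gt.adp, abs=0.2)

    def test_symmetric_triangle_half_width_by_similar_triangles(self):
        rate = 100_000.0
        base_ms = 2.0
        t = np.arange(0, 0.02, 1 / rate) * 1e3  # ms
        v = np.full(t.size, -60.0)
        apex = 40.0
        rise = (t >= 5.0) & (t < 5.0 + base_ms / 2)
        fall = (t >= 5.0 + base_ms / 2) & (t < 5.0 + base_ms)
        v[rise] = -60.0 + apex * (t[rise] - 5.0) / (base_ms / 2)
        v[fall] = -60.0 + apex * (5.0 + base_ms - t[fall]) / (base_ms / 2)
        sw = sp.TimeSeries(v, rate=rate, units="mV")
        ap = sp.ap_features(sw, onset=5.0e-3)
        assert ap.half_width == pytest.approx(base_ms / 2, rel=0.01)

    def test_spike_at_trace_end_incomplete_window(self, noiseless_cell):
        _, family, truth = noiseless_cell
        s = next(s for s in truth["per_sweep"] if s["n_spikes"] > 0)
        sw_full = family.sweep_for(s["amplitude"])
        onset = s["spike_onsets"][0]
        i_on = int(round(onset * sw_full.rate))
        i_peak = i_on + int(np.argmax(sw_full.samples[i_on : i_on + 200]))
        sw = sp.TimeSeries(sw_full.samples[: i_peak + 2], rate=sw_full.rate, units="mV")
        with pytest.raises(ValidationError, match="incomplete AHP window"):
            sp.ap_features(sw, onset)

    def test_constant_offset_shifts_only_threshold(self, noiseless_cell):
        _, family, truth = noiseless_cell
        s = next(s for s in truth["per_sweep"] if s["n_spikes"] >= 2)
        sw = family.sweep_for(s["amplitude"])
        tr = sp.detect_spikes(sw)
        a = sp.ap_features(sw, tr.times[0], tr.times[1])
        shifted = sp.TimeSeries(sw.samples + 7.5, rate=sw.rate, units="mV")
        b = sp.ap_features(shifted, tr.times[0], tr.times[1])
        assert b.threshold_v == pytest.approx(a.threshold_v + 7.5, abs=1e-9)
        for f in ("amplitude", "rise_10_90", "half_width", "fahp", "mahp",
                  "time_to_mahp", "adp"):
            assert getattr(b, f) == pytest.approx(getattr(a, f), abs=1e-9)


class TestEstimatePassive:
    def test_noiseless_recovery_sub_permille(self, noiseless_cell):
        cfg, family, _ = noiseless_cell
        p = sp.estimate_passive(family)
        assert p.rmp == pytest.approx(cfg.rmp, abs=1e-3)
        assert p.r_in == pytest.approx(cfg.r_in, rel=1e-3)
        assert p.tau_m == pytest.approx(cfg.tau_m, rel=1e-3)

    def test_noisy_recovery_within_5pct(self):
        cfg = sp.CellSimConfig(noise_sd=0.3, seed=21)
        family, _ = sp.simulate_current_steps(cfg)
        p = sp.estimate_passive(family, smooth_hz=2000.0)
        assert p.rmp == pytest.approx(cfg.rmp, rel=0.05)
        assert p.r_in == pytest.approx(cfg.r_in, rel=0.05)
        assert p.tau_m == pytest.approx(cfg.tau_m, rel=0.05)

    def test_insufficient_subthreshold_sweeps_rejected(self):
        cfg = sp.CellSimConfig(noise_sd=0.0, rate=10_000.0)
        proto = sp.StepProtocol(step_onset=0.2, step_duration=0.5,
                                amplitudes=np.array([-100.0, 0.0]),
                                inter_sweep_interval=1.0)
        family, _ = sp.simulate_current_steps(cfg, proto)
        with pytest.raises(ValidationError, match="insufficient subthreshold"):
            sp.estimate_passive(family)


class TestFiringPattern:
    def test_rheobase_exact_on_grid(self, noiseless_cell):
        _, family, truth = noiseless_cell
        fp = sp.firing_pattern(family)
        assert fp.rheobase == truth["rheobase_grid"] == 130.0

    def test_fi_counts_match_ground_truth(self, noiseless_cell):
        _, family, truth = noiseless_cell
        fp = sp.firing_pattern(family)
        assert np.array_equal(fp.fi_rates, truth["fi_rates"])
        assert fp.max_rate == truth["max_rate"]
        assert fp.current_at_max == truth["current_at_max"]
        assert np.all(fp.fi_rates >= 0)
        assert fp.rheobase <= fp.current_at_max <= (fp.block_current or np.inf)

    def test_block_detected_at_planted_current(self, noiseless_cell):
        cfg, family, _ = noiseless_cell
        fp = sp.firing_pattern(family)
        assert fp.block_current == cfg.block_current

    def test_equal_isis_give_unit_adaptation_ratios(self):
        # constructed grid-aligned spikes: detected ISIs identical, ratios exactly 1
        rate = 20_000.0
        t = np.arange(0, 3.5, 1 / rate)

        def spike_sweep(onsets):
            v = np.full(t.size, -65.0)
            for on in onsets:
                i = int(round(on * rate))
                v[i : i + 10] = -65.0 + np.linspace(0, 60, 10)
                v[i + 10 : i + 20] = -67.0
            return sp.TimeSeries(v, rate=rate, units="mV")

        proto = sp.StepProtocol(step_onset=0.5,
                                amplitudes=np.array([0.0, 120.0, 140.0]))
        flat = sp.TimeSeries(np.full(t.size, -65.0), rate=rate, units="mV")
        family = sp.SweepFamily(protocol=proto, sweeps=[
            flat, spike_sweep([0.8]), spike_sweep(0.6 + 0.1 * np.arange(8))])
        with pytest.raises(ValidationError):
            # no hyperpolarizing sweep: passive estimation must refuse
            sp.estimate_passive(family)
        fp = sp.firing_pattern(family)
        assert fp.early_adaptation == 1.0
        assert fp.late_adaptation == 1.0

    def test_planted_adaptation_ratio_recovered(self):
        cfg = sp.CellSimConfig(adaptation_strength=2.0, noise_sd=0.0)
        family, truth = sp.simulate_current_steps(cfg)
        fp = sp.firing_pattern(family)
        assert truth["late_adaptation"] > 1.0
        assert fp.late_adaptation == pytest.approx(truth["late_adaptation"], rel=0.05)
        assert fp.early_adaptation == pytest.approx(truth["early_adaptation"], rel=0.05)

    def test_rheobase_invariant_to_extra_subthreshold_sweeps(self):
        cfg = sp.CellSimConfig(noise_sd=0.0)
        small = sp.StepProtocol(step_onset=0.5, amplitudes=np.arange(0.0, 301.0, 20.0))
        big = sp.StepProtocol(step_onset=0.5, amplitudes=np.arange(-100.0, 301.0, 20.0))
        fam_a, _ = sp.simulate_current_steps(cfg, small)
        fam_b, _ = sp.simulate_current_steps(cfg, big)
        assert sp.firing_pattern(fam_a).rheobase == sp.firing_pattern(fam_b).rheobase

    def test_no_spiking_family_has_no_rheobase(self):
        cfg = sp.CellSimConfig(noise_sd=0.0, rate=10_000.0)
        proto = sp.StepProtocol(step_onset=0.2, step_duration=0.5,
                                amplitudes=np.array([-100.0, -50.0, 0.0, 50.0]),
                                inter_sweep_interval=1.0)
        family, _ = sp.simulate_current_steps(cfg, proto)
        with pytest.raises(ValidationError, match="no rheobase"):
            sp.firing_pattern(family)
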