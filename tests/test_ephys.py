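"""Electrophysiological feature extraction against planted ground truth."""

import numpy as np
import pytest

from patchseq.ephys import (DetectedSpikes, StimulusProtocol, Sweep, SweepSet,
                            adaptation_features, assemble_analysis_vector,
                            burstiness, classify_isis, detect_bursts,
                            detect_spikes, extract_features, firing_statistics,
                            isi_coefficient_of_variation, passive_features,
                            rebound_features, rheobase, sag_features,
                            select_highest_firing_trace, wildness)
from patchseq.ephys import ANALYSIS_FEATURES, EphysFeatures, _ratio_indices
from patchseq.synthetic import (APShape, TraceSpec, generate_sweep_set,
                                poisson_spike_train)

DT = 5e-5


def make_sweep(voltage, current=-100.0, repeat=0):
    return Sweep(sample_period_s=DT, voltage_mV=np.asarray(voltage, float),
                 current_pA=current, repeat_index=repeat)


def step_trace(protocol, v_rest, v_during, v_after=None, duration=1.2):
    """Piecewise-constant trace: rest / pulse / post."""
    t = np.arange(0.0, duration, DT)
    v = np.full(t.size, float(v_rest))
    v[(t >= protocol.onset_s) & (t < protocol.offset_s)] = v_during
    if v_after is not None:
        v[t >= protocol.offset_s] = v_after
    return v


# --------------------------------------------------------------------------
# Spike detection
# --------------------------------------------------------------------------

class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self, protocol):
        sweep = make_sweep(np.full(24000, -70.0), current=100.0)
        assert len(detect_spikes(sweep, protocol)) == 0

    def test_planted_spikes_found_at_planted_times(self, protocol):
        times = [0.15, 0.3, 0.55]
        spec = TraceSpec(spike_times_s={120.0: times}, seed=0)
        ss, _ = generate_sweep_set(
            spec, StimulusProtocol(current_steps_pA=(-100.0, 120.0)))
        sweep = [s for s in ss if s.current_pA == 120.0][0]
        d = detect_spikes(sweep, protocol)
        assert len(d) == 3
        assert np.all(np.abs(d.threshold_t - times) < 1e-3)

    def test_pre_window_spike_is_counted_in_pre_window(self, protocol):
        spec = TraceSpec(spike_times_s={120.0: [0.05]}, seed=0)
        ss, _ = generate_sweep_set(
            spec, StimulusProtocol(current_steps_pA=(-100.0, 120.0)))
        sweep = [s for s in ss if s.current_pA == 120.0][0]
        d = detect_spikes(sweep, protocol)
        assert d.n_pre_window() == 1
        assert d.n_in_window() == 0


# --------------------------------------------------------------------------
# Passive features
# --------------------------------------------------------------------------

class TestPassive:
    def test_input_resistance_from_noiseless_step(self, protocol):
        spec = TraceSpec(resting_potential_mV=-70.0,
                         input_resistance_MOhm=50.0, membrane_tau_ms=5.0)
        ss, _ = generate_sweep_set(
            spec, StimulusProtocol(current_steps_pA=(-100.0,)))
        v_rest, r_in, tau = passive_features(ss, protocol)
        assert v_rest == pytest.approx(-70.0, abs=0.01)
        assert r_in == pytest.approx(50.0, rel=0.01)

    def test_tau_recovered_from_noiseless_exponential(self, protocol):
        spec = TraceSpec(membrane_tau_ms=20.0, sag_amplitude_mV=0.0)
        ss, _ = generate_sweep_set(
            spec, StimulusProtocol(current_steps_pA=(-100.0,)))
        _, _, tau = passive_features(ss, protocol)
        assert tau == pytest.approx(20.0, rel=0.05)

    def test_median_over_two_sweeps(self, protocol):
        v40 = step_trace(protocol, -70.0, -74.0)   # R = 40 MOhm at -100 pA
        v60 = step_trace(protocol, -70.0, -76.0)   # R = 60 MOhm
        ss = SweepSet([make_sweep(v40, -100.0, 0), make_sweep(v60, -100.0, 1)])
        _, r_in, _ = passive_features(ss, protocol)
        assert r_in == pytest.approx(50.0, rel=0.01)

    def test_no_hyperpolarizing_sweep_is_undefined(self, protocol):
        ss = SweepSet([make_sweep(np.full(24000, -70.0), 100.0)])
        v_rest, r_in, tau = passive_features(ss, protocol)
        assert np.isnan(v_rest) and np.isnan(r_in) and np.isnan(tau)


# --------------------------------------------------------------------------
# Rheobase
# --------------------------------------------------------------------------

class TestRheobase:
    def test_collinear_counts_give_exact_intercept(self):
        counts = {100.0: 0, 120.0: 1, 140.0: 2, 160.0: 3, 180.0: 4, 200.0: 5}
        assert rheobase(counts) == pytest.approx(100.0, abs=1e-6)

    def test_single_spiking_sweep_falls_back_to_its_current(self):
        assert rheobase({280.0: 0, 300.0: 1}) == 300.0

    def test_intercept_outside_interval_falls_back(self):
        # line through (60,5),(80,9),... crosses zero at 35 pA, outside the
        # [40, 60] interval -> the lowest spiking current is used
        counts = {40.0: 0, 60.0: 5, 80.0: 9, 100.0: 13, 120.0: 17, 140.0: 21}
        assert rheobase(counts) == pytest.approx(60.0)

    def test_no_spiking_sweep_is_undefined(self):
        assert np.isnan(rheobase({100.0: 0, 120.0: 0}))


# --------------------------------------------------------------------------
# AP shape on planted templates
# --------------------------------------------------------------------------

class TestAPShape:
    def test_planted_shape_recovered(self, regular_firing_cell, protocol):
        _, _, spec = regular_firing_cell
        ss, _ = generate_sweep_set(spec, protocol)
        f = extract_features(ss, protocol)
        shape = spec.ap_shape
        assert f.AP_threshold == pytest.approx(shape.threshold_mV, abs=0.2)
        assert f.AP_amplitude == pytest.approx(shape.amplitude_mV, abs=0.2)
        assert f.AHP == pytest.approx(shape.ahp_mV, abs=0.2)
        # width within one sample period
        assert f.AP_width == pytest.approx(shape.halfwidth_ms, abs=DT * 1000)
        assert f.UDR == pytest.approx(
            shape.upstroke_Vps / shape.downstroke_Vps, rel=0.08)
        # first spike planted 10 ms after onset
        assert f.latency == pytest.approx(10.0, abs=0.2)

    def test_amplitude_is_peak_minus_threshold(self, regular_firing_cell,
                                               protocol):
        ss, _, spec = regular_firing_cell
        sweep = [s for s in ss if s.current_pA == 120.0][0]
        d = detect_spikes(sweep, protocol)
        assert d.peak_v[0] - d.threshold_v[0] == pytest.approx(
            spec.ap_shape.amplitude_mV, abs=0.2)


# --------------------------------------------------------------------------
# Adaptation
# --------------------------------------------------------------------------

class TestAdaptation:
    def test_ratio_indices(self):
        a, avg = _ratio_indices(np.array([0.1, 0.2]))
        assert a == pytest.approx(2.0)
        a, avg = _ratio_indices(np.array([50.0, 45.0, 40.5]))
        assert a == pytest.approx(0.9)
        assert avg == pytest.approx(0.9)

    def test_isi_adaptation_from_planted_train(self, protocol):
        spec = TraceSpec(spike_times_s={120.0: [0.15, 0.25, 0.45]}, seed=0)
        ss, _ = generate_sweep_set(
            spec, StimulusProtocol(current_steps_pA=(-100.0, 120.0)))
        spikes = {i: detect_spikes(s, protocol) for i, s in enumerate(ss.sweeps)}
        out = adaptation_features(ss, protocol, spikes)
        assert out["ISI_adaptation"] == pytest.approx(2.0, abs=0.01)

    def test_regular_train_has_unit_indices(self, regular_firing_cell,
                                            protocol):
        ss, _, _ = regular_firing_cell
        f = extract_features(ss, protocol)
        assert f.ISI_adaptation == pytest.approx(1.0, abs=1e-3)
        assert f.ISI_avg_adaptation == pytest.approx(1.0, abs=1e-3)
        assert f.AP_amp_adaptation == pytest.approx(1.0, abs=1e-3)


# --------------------------------------------------------------------------
# Highest firing trace and firing statistics
# --------------------------------------------------------------------------

class TestFiring:
    def _sweepset(self, protocol, spikes):
        proto = StimulusProtocol(
            current_steps_pA=tuple(sorted({-100.0, *spikes})))
        spec = TraceSpec(spike_times_s=spikes, seed=0)
        ss, _ = generate_sweep_set(spec, proto)
        return ss

    def test_first_of_max_count_wins(self, protocol):
        spikes = {100.0: [0.15, 0.3],
                  120.0: list(0.12 + np.linspace(0, 0.4, 8)),
                  140.0: list(0.12 + np.linspace(0, 0.4, 8))}
        ss = self._sweepset(protocol, spikes)
        det = {i: detect_spikes(s, protocol) for i, s in enumerate(ss.sweeps)}
        idx = select_highest_firing_trace(ss, protocol, det)
        assert ss.sweeps[idx].current_pA == 120.0

    def test_pre_window_ap_excludes_sweep(self, protocol):
        spikes = {100.0: list(0.12 + np.linspace(0, 0.4, 5)),
                  140.0: [0.05] + list(0.12 + np.linspace(0, 0.4, 9))}
        ss = self._sweepset(protocol, spikes)
        det = {i: detect_spikes(s, protocol) for i, s in enumerate(ss.sweeps)}
        idx = select_highest_firing_trace(ss, protocol, det)
        assert ss.sweeps[idx].current_pA == 100.0

    def test_sfa_six_four_split(self, protocol):
        # 6 APs in the first half of the window, 4 in the second
        times = list(np.linspace(0.12, 0.38, 6)) + list(np.linspace(0.42, 0.68, 4))
        ss = self._sweepset(protocol, {200.0: times})
        det = {i: detect_spikes(s, protocol) for i, s in enumerate(ss.sweeps)}
        idx = select_highest_firing_trace(ss, protocol, det)
        out = firing_statistics(ss, protocol, det, idx)
        assert out["max_num_APs"] == 10
        assert out["SFA"] == pytest.approx(4.0 / 6.0, abs=1e-6)

    def test_regular_train_has_zero_isi_cv(self, regular_firing_cell, protocol):
        ss, _, _ = regular_firing_cell
        f = extract_features(ss, protocol)
        assert f.ISI_CV == pytest.approx(0.0, abs=1e-2)
        assert f.AP_CV == pytest.approx(0.0, abs=1e-3)

    def test_poisson_train_isi_cv_near_one(self):
        train = poisson_spike_train(50.0, 600.0, seed=11)
        cv = isi_coefficient_of_variation(np.diff(train))
        assert cv == pytest.approx(1.0, rel=0.02)


# --------------------------------------------------------------------------
# Sag and rebound
# --------------------------------------------------------------------------

class TestSagRebound:
    def test_rectangular_sag_ratio_time_area(self, protocol):
        t = np.arange(0.0, 1.2, DT)
        v = np.full(t.size, -70.0)
        stim = (t >= protocol.onset_s) & (t < protocol.offset_s)
        v[stim] = -80.0
        dip = (t >= 0.2) & (t < 0.22)   # 5 mV x 20 ms rectangular excursion
        v[dip] = -85.0
        ss = SweepSet([make_sweep(v, -100.0)])
        ratio, sag_time, sag_area = sag_features(ss, protocol)
        assert ratio == pytest.approx(1.5, abs=0.01)
        assert sag_time == pytest.approx(20.0, abs=0.2)
        assert sag_area == pytest.approx(100.0, rel=0.02)

    def test_small_sag_zeroing_rule_is_exact(self, protocol):
        t = np.arange(0.0, 1.2, DT)
        v = np.full(t.size, -70.0)
        stim = (t >= protocol.onset_s) & (t < protocol.offset_s)
        v[stim] = -80.0
        v[(t >= 0.2) & (t < 0.22)] = -82.0   # 2 mV < 4 mV rule
        ss = SweepSet([make_sweep(v, -100.0)])
        _, sag_time, sag_area = sag_features(ss, protocol)
        assert sag_time == 0.0 and sag_area == 0.0

    def test_rebound_plateau(self, protocol):
        v = step_trace(protocol, -70.0, -80.0, v_after=-65.0)
        ss = SweepSet([make_sweep(v, -100.0)])
        det = {0: detect_spikes(ss.sweeps[0], protocol)}
        reb, n = rebound_features(ss, protocol, det, v_rest=-70.0)
        assert reb == pytest.approx(5.0, abs=0.01)
        assert n == 0

    def test_no_crossing_gives_exact_zero_rebound(self, protocol):
        v = step_trace(protocol, -70.0, -80.0, v_after=-75.0)
        ss = SweepSet([make_sweep(v, -100.0)])
        det = {0: detect_spikes(ss.sweeps[0], protocol)}
        reb, n = rebound_features(ss, protocol, det, v_rest=-70.0)
        assert reb == 0.0 and n == 0.0

    def test_rebound_spikes_counted(self):
        proto = StimulusProtocol(current_steps_pA=(-200.0,))
        spec = TraceSpec(rebound_mV=6.0, sag_amplitude_mV=3.0,
                         spike_times_s={-200.0: [0.72, 0.76]}, seed=0)
        ss, _ = generate_sweep_set(spec, proto)
        det = {i: detect_spikes(s, proto) for i, s in enumerate(ss.sweeps)}
        _, n = rebound_features(ss, proto, det, v_rest=-70.0)
        assert n == 2

    def test_planted_sag_recovered(self, regular_firing_cell, protocol):
        ss, truth, _ = regular_firing_cell
        ratio, sag_time, _ = sag_features(ss, protocol)
        assert ratio == pytest.approx(truth.sag_ratio, rel=0.02)
        assert sag_time > 0


# --------------------------------------------------------------------------
# Burstiness and wildness
# --------------------------------------------------------------------------

class TestBurstiness:
    def test_detour_direct_sequence_flags_one_burst(self):
        labels = ["detour", "direct", "direct", "detour"]
        assert detect_bursts(labels) == [(0, 2)]

    def test_pauselike_isi_never_joins_a_burst(self):
        isis = np.array([0.05, 0.01, 0.5, 0.05])
        adp = np.array([1.0, 0.0, 0.0, 0.0])
        labels = classify_isis(isis, adp, np.zeros(4))
        assert labels[2] == "pauselike"
        bursts = detect_bursts(labels)
        assert all(not (a <= 2 <= b) for a, b in bursts)

    def test_burstiness_value_from_constructed_train(self, protocol):
        # intra-burst min ISI 10 ms vs extra-burst 50 ms -> (100-20)/120
        thr_t = np.array([0.15, 0.20, 0.21, 0.22, 0.27])
        n = thr_t.size
        fake = DetectedSpikes(
            threshold_idx=np.zeros(n, int), threshold_t=thr_t,
            threshold_v=np.full(n, -42.0), peak_idx=np.zeros(n, int),
            peak_t=thr_t + 1e-3, peak_v=np.full(n, 18.0),
            trough_idx=np.zeros(n, int), trough_t=thr_t + 2e-3,
            trough_v=np.full(n, -54.0),
            adp_mV=np.array([1.0, 0.0, 0.0, 1.0, 0.0]),
            isi_drawdown_mV=np.zeros(n - 1),
            onset_s=protocol.onset_s, offset_s=protocol.offset_s)
        ss = SweepSet([make_sweep(np.full(24000, -60.0), 120.0)])
        value = burstiness(ss, protocol, {0: fake})
        assert value == pytest.approx((100.0 - 20.0) / 120.0, abs=1e-9)

    def test_regular_train_is_not_bursty(self, regular_firing_cell, protocol):
        ss, _, _ = regular_firing_cell
        f = extract_features(ss, protocol)
        assert f.burstiness == 0.0


class TestWildness:
    def test_zero_without_out_of_window_firing(self, regular_firing_cell,
                                               protocol):
        ss, _, _ = regular_firing_cell
        f = extract_features(ss, protocol)
        assert f.wildness == 0.0

    def test_excess_aps_on_excluded_sweep(self, protocol):
        spikes = {100.0: list(np.linspace(0.12, 0.6, 22)),
                  120.0: [0.05] + list(np.linspace(0.12, 0.6, 30))}
        proto = StimulusProtocol(current_steps_pA=(-100.0, 100.0, 120.0))
        spec = TraceSpec(spike_times_s=spikes, seed=0)
        ss, _ = generate_sweep_set(spec, proto)
        det = {i: detect_spikes(s, proto) for i, s in enumerate(ss.sweeps)}
        hi = select_highest_firing_trace(ss, proto, det)
        assert ss.sweeps[hi].current_pA == 100.0
        assert wildness(ss, proto, det, hi) == 8.0


# --------------------------------------------------------------------------
# Analysis vector
# --------------------------------------------------------------------------

class TestAnalysisVector:
    def test_length_and_log_transform(self, regular_firing_cell, protocol):
        # mild noise keeps the CV features strictly positive for the log
        _, _, spec = regular_firing_cell
        spec_noisy = TraceSpec(**{**spec.__dict__, "noise_sd_mV": 0.2})
        ss, _ = generate_sweep_set(spec_noisy, protocol)
        f = extract_features(ss, protocol)
        vec, complete = assemble_analysis_vector(f)
        assert vec.shape == (17,)
        assert complete
        i = ANALYSIS_FEATURES.index("latency")
        assert vec[i] == pytest.approx(np.log(f.latency))

    def test_missing_feature_flags_incomplete(self):
        f = EphysFeatures(latency=10.0)
        vec, complete = assemble_analysis_vector(f)
        assert not complete

    def test_median_features_invariant_to_sweep_order(self, protocol,
                                                      regular_firing_cell):
        ss, _, _ = regular_firing_cell
        shuffled = SweepSet(list(reversed(ss.sweeps)))
        f1 = extract_features(ss, protocol)
        f2 = extract_features(shuffled, protocol)
        for k, v in f1.as_dict().items():
            v2 = f2.as_dict()[k]
            assert (np.isnan(v) and np.isnan(v2)) or v == pytest.approx(v2)
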