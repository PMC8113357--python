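"""Electrophysiological feature extraction from current-clamp sweep sets.

A cell is probed with a family of 600-ms square current pulses (default
-200 pA .. +1380 pA in 20-pA steps).  From the resulting voltage traces we
extract 29 named features -- passive membrane properties, action-potential
(AP) shape, firing statistics, sag/rebound quantification and burstiness --
and derive the standardized 17-feature vector used in all downstream
statistical analyses.

Conventions: time in seconds, voltage in mV, current in pA, input resistance
in MOhm, time constant and AP width in ms.  Undefined features are NaN and
propagate as missing values; only where an explicit zeroing rule applies
(sag, rebound, wildness) is an exact 0.0 returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, savgol_filter
from sklearn.linear_model import LinearRegression, RANSACRegressor

__all__ = [
    "StimulusProtocol",
    "Sweep",
    "SweepSet",
    "SpikeDetectionParams",
    "DetectedSpikes",
    "EphysFeatures",
    "ANALYSIS_FEATURES",
    "LOG_TRANSFORMED_FEATURES",
    "detect_spikes",
    "passive_features",
    "rheobase",
    "ap_shape_features",
    "adaptation_features",
    "select_highest_firing_trace",
    "firing_statistics",
    "sag_features",
    "rebound_features",
    "burstiness",
    "wildness",
    "extract_features",
    "assemble_analysis_vector",
    "isi_coefficient_of_variation",
]


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

def default_current_steps() -> tuple[float, ...]:
    return tuple(float(c) for c in range(-200, 1381, 20))


@dataclass(frozen=True)
class StimulusProtocol:
    """Square-pulse stimulation protocol.

    The default mirrors the recording paradigm: pulse onset at 0.1 s,
    600-ms duration, currents from -200 pA to +1380 pA in 20-pA increments,
    1.3-s inter-sweep interval.
    """

    onset_s: float = 0.1
    duration_s: float = 0.6
    current_steps_pA: tuple[float, ...] = field(default_factory=default_current_steps)
    inter_sweep_interval_s: float = 1.3

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("stimulus duration must be positive")
        steps = np.asarray(self.current_steps_pA, dtype=float)
        if steps.size > 1 and np.any(np.diff(steps) <= 0):
            raise ValueError("current steps must be strictly increasing")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(eq=False)
class Sweep:
    """One current-clamp trace: uniformly sampled voltage plus the step current."""

    sample_period_s: float
    voltage_mV: np.ndarray
    current_pA: float
    repeat_index: int = 0

    def __post_init__(self) -> None:
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
        if self.sample_period_s <= 0:
            raise ValueError("sample period must be positive")

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.voltage_mV.size) * self.sample_period_s

    @property
    def duration_s(self) -> float:
        return self.voltage_mV.size * self.sample_period_s


@dataclass
class SweepSet:
    """All sweeps recorded from one cell under a common protocol."""

    sweeps: list[Sweep]

    def __post_init__(self) -> None:
        # canonical order: increasing current, then repeat index
        self.sweeps = sorted(self.sweeps, key=lambda s: (s.current_pA, s.repeat_index))

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self):
        return iter(self.sweeps)

    def hyperpolarizing(self) -> list[Sweep]:
        return [s for s in self.sweeps if s.current_pA < 0]

    def depolarizing(self) -> list[Sweep]:
        return [s for s in self.sweeps if s.current_pA > 0]

    def first_repeats(self, sweeps: Sequence[Sweep] | None = None) -> list[Sweep]:
        """One sweep per current step: the lowest repeat index."""
        pool = self.sweeps if sweeps is None else list(sweeps)
        seen: dict[float, Sweep] = {}
        for s in pool:
            if s.current_pA not in seen or s.repeat_index < seen[s.current_pA].repeat_index:
                seen[s.current_pA] = s
        return [seen[c] for c in sorted(seen)]


@dataclass(frozen=True)
class SpikeDetectionParams:
    """Declared spike-detection defaults (Allen-SDK-style convention).

    An AP is a voltage peak above ``peak_height_mV`` whose preceding rising
    phase exceeds ``dvdt_threshold_Vps``; the threshold point is where dV/dt
    first crosses that rate.
    """

    dvdt_threshold_Vps: float = 20.0
    peak_height_mV: float = -20.0
    min_prominence_mV: float = 10.0
    trough_search_s: float = 0.1
    adp_search_s: float = 0.05
    adp_min_prominence_mV: float = 0.5


@dataclass
class DetectedSpikes:
    """Per-AP landmarks for one sweep plus stimulus-window bookkeeping."""

    threshold_idx: np.ndarray
    threshold_t: np.ndarray
    threshold_v: np.ndarray
    peak_idx: np.ndarray
    peak_t: np.ndarray
    peak_v: np.ndarray
    trough_idx: np.ndarray
    trough_t: np.ndarray
    trough_v: np.ndarray
    adp_mV: np.ndarray
    isi_drawdown_mV: np.ndarray  # max voltage drop between trough i and threshold i+1
    onset_s: float
    offset_s: float

    def __len__(self) -> int:
        return self.threshold_t.size

    @property
    def amplitudes_mV(self) -> np.ndarray:
        return self.peak_v - self.threshold_v

    def in_window(self) -> np.ndarray:
        return (self.threshold_t >= self.onset_s) & (self.threshold_t <= self.offset_s)

    def n_in_window(self) -> int:
        return int(np.count_nonzero(self.in_window()))

    def n_pre_window(self) -> int:
        m = (self.threshold_t >= self.onset_s - 0.1) & (self.threshold_t < self.onset_s)
        return int(np.count_nonzero(m))

    def n_post_window(self) -> int:
        m = (self.threshold_t > self.offset_s) & (self.threshold_t <= self.offset_s + 0.2)
        return int(np.count_nonzero(m))

    def window_isis_s(self) -> np.ndarray:
        t = self.threshold_t[self.in_window()]
        return np.diff(t)

    def window_amplitudes(self) -> np.ndarray:
        return self.amplitudes_mV[self.in_window()]


# --------------------------------------------------------------------------
# Spike detection
# --------------------------------------------------------------------------

def detect_spikes(
    sweep: Sweep,
    protocol: StimulusProtocol,
    params: SpikeDetectionParams | None = None,
) -> DetectedSpikes:
    """Locate APs on one sweep: threshold, peak, trough and ADP per spike.

    Threshold is the first point before the peak where dV/dt exceeds the
    detection rate (default 20 V/s); the trough is the voltage minimum
    between the peak and the next threshold (or within the trough search
    window).  ADP is the height of the first local maximum after the trough,
    zero if the recovery is monotone.
    """
    p = params or SpikeDetectionParams()
    v = sweep.voltage_mV
    dt = sweep.sample_period_s
    dvdt = np.gradient(v, dt) / 1000.0  # V/s

    peak_idx, _ = find_peaks(
        v, height=p.peak_height_mV, prominence=p.min_prominence_mV
    )

    thr_idx: list[int] = []
    kept_peaks: list[int] = []
    prev_bound = 0
    for pk in peak_idx:
        window = slice(prev_bound, pk + 1)
        cand = np.nonzero(dvdt[window] >= p.dvdt_threshold_Vps)[0]
        if cand.size == 0:
            continue  # slow hump, not an AP
        thr_idx.append(prev_bound + int(cand[0]))
        kept_peaks.append(int(pk))
        prev_bound = int(pk)

    thr = np.asarray(thr_idx, dtype=int)
    pks = np.asarray(kept_peaks, dtype=int)
    n = pks.size

    trough = np.zeros(n, dtype=int)
    adp = np.zeros(n)
    drawdown = np.zeros(max(n - 1, 0))
    max_trough = max(int(round(p.trough_search_s / dt)), 1)
    for i in range(n):
        stop = thr[i + 1] if i + 1 < n else min(pks[i] + max_trough, v.size)
        stop = max(stop, pks[i] + 2)
        trough[i] = pks[i] + int(np.argmin(v[pks[i]:stop]))
        # ADP: first local max after the trough, before the next threshold
        adp_stop = thr[i + 1] if i + 1 < n else min(
            trough[i] + int(round(p.adp_search_s / dt)), v.size
        )
        seg = v[trough[i]:adp_stop]
        if seg.size >= 3:
            local_max, _ = find_peaks(seg, prominence=p.adp_min_prominence_mV)
            if local_max.size:
                adp[i] = seg[local_max[0]] - v[trough[i]]
        if i + 1 < n:
            span = v[trough[i]:thr[i + 1] + 1]
            if span.size >= 2:
                # max drawdown: largest drop from a running max
                drawdown[i] = float(np.max(np.maximum.accumulate(span) - span))

    t = np.arange(v.size) * dt
    return DetectedSpikes(
        threshold_idx=thr,
        threshold_t=t[thr] if n else np.empty(0),
        threshold_v=v[thr] if n else np.empty(0),
        peak_idx=pks,
        peak_t=t[pks] if n else np.empty(0),
        peak_v=v[pks] if n else np.empty(0),
        trough_idx=trough,
        trough_t=t[trough] if n else np.empty(0),
        trough_v=v[trough] if n else np.empty(0),
        adp_mV=adp,
        isi_drawdown_mV=drawdown,
        onset_s=protocol.onset_s,
        offset_s=protocol.offset_s,
    )


def _window_mean(sweep: Sweep, t0: float, t1: float) -> float:
    i0 = max(int(round(t0 / sweep.sample_period_s)), 0)
    i1 = min(int(round(t1 / sweep.sample_period_s)), sweep.voltage_mV.size)
    return float(np.mean(sweep.voltage_mV[i0:i1]))


def _resting_potential(sweep: Sweep, protocol: StimulusProtocol) -> float:
    return _window_mean(sweep, protocol.onset_s - 0.1, protocol.onset_s)


def _steady_state(sweep: Sweep, protocol: StimulusProtocol) -> float:
    return _window_mean(sweep, protocol.offset_s - 0.1, protocol.offset_s)


# --------------------------------------------------------------------------
# Passive features
# --------------------------------------------------------------------------

def _fit_tau_ms(sweep: Sweep, protocol: StimulusProtocol) -> float:
    """Membrane time constant from an exponential fit onset -> first local
    minimum of the 5-ms-smoothed trace."""
    dt = sweep.sample_period_s
    v = sweep.voltage_mV
    i_on = int(round(protocol.onset_s / dt))
    i_off = int(round(protocol.offset_s / dt))
    seg = v[i_on:i_off]
    win = max(int(round(0.005 / dt)) | 1, 5)  # odd, >= 5 samples
    smooth = savgol_filter(seg, win, 2) if seg.size > win else seg
    minima, _ = find_peaks(-smooth)
    i_min = int(minima[0]) if minima.size else int(np.argmin(smooth))
    if i_min < 5:
        return float("nan")
    tt = np.arange(i_min + 1) * dt
    vv = seg[: i_min + 1]

    def model(t, a, tau, c):
        return a * np.exp(-t / tau) + c

    a0 = vv[0] - vv[-1]
    tau0 = max(tt[-1] / 3.0, dt)
    try:
        popt, _ = curve_fit(
            model, tt, vv, p0=(a0, tau0, vv[-1]),
            bounds=([-np.inf, dt / 10, -np.inf], [np.inf, 10.0, np.inf]),
            maxfev=10000,
        )
    except RuntimeError:
        return float("nan")
    return float(popt[1] * 1000.0)


def passive_features(
    sweep_set: SweepSet, protocol: StimulusProtocol
) -> tuple[float, float, float]:
    """(V_rest [mV], R_input [MOhm], tau [ms]): medians over hyperpolarizing sweeps.

    R_input is (steady-state - resting) / injected current per sweep; the
    steady state is the mean voltage over the last 100 ms of the pulse.
    """
    hyper = sweep_set.hyperpolarizing()
    if not hyper:
        return float("nan"), float("nan"), float("nan")
    v_rests, r_inputs, taus = [], [], []
    for s in hyper:
        vr = _resting_potential(s, protocol)
        ss = _steady_state(s, protocol)
        v_rests.append(vr)
        r_inputs.append((ss - vr) / s.current_pA * 1000.0)  # mV/pA -> GOhm -> MOhm
        taus.append(_fit_tau_ms(s, protocol))
    return (
        float(np.median(v_rests)),
        float(np.median(r_inputs)),
        float(np.nanmedian(taus)),
    )


# --------------------------------------------------------------------------
# Rheobase
# --------------------------------------------------------------------------

def rheobase(spike_counts_by_current: dict[float, int]) -> float:
    """Rheobase (pA) from a robust line fit of spike count versus current.

    Fits RANSAC regression over the five lowest depolarizing currents with
    non-zero spike count and takes the x-intercept, clamped to the interval
    between the highest zero-count current and the lowest spiking current;
    outside that interval the lowest spiking current is returned.
    """
    currents = sorted(c for c in spike_counts_by_current if c > 0)
    spiking = [c for c in currents if spike_counts_by_current[c] > 0]
    if not spiking:
        return float("nan")
    lowest_spiking = spiking[0]
    zeros_below = [c for c in currents if spike_counts_by_current[c] == 0 and c < lowest_spiking]
    lo = max(zeros_below) if zeros_below else -np.inf
    fit_currents = spiking[:5]
    if len(fit_currents) < 2:
        return float(lowest_spiking)
    x = np.asarray(fit_currents, dtype=float).reshape(-1, 1)
    y = np.asarray([spike_counts_by_current[c] for c in fit_currents], dtype=float)
    try:
        reg = RANSACRegressor(estimator=LinearRegression(), random_state=0)
        reg.fit(x, y)
        slope = float(reg.estimator_.coef_[0])
        icpt = float(reg.estimator_.intercept_)
    except ValueError:
        return float(lowest_spiking)
    if slope <= 0:
        return float(lowest_spiking)
    x0 = -icpt / slope
    if lo - 1e-9 <= x0 <= lowest_spiking + 1e-9:
        return float(min(max(x0, lo), lowest_spiking))
    return float(lowest_spiking)


# --------------------------------------------------------------------------
# AP shape
# --------------------------------------------------------------------------

def _half_width_ms(sweep: Sweep, spikes: DetectedSpikes, i: int) -> float:
    v = sweep.voltage_mV
    dt = sweep.sample_period_s
    half = spikes.threshold_v[i] + 0.5 * (spikes.peak_v[i] - spikes.threshold_v[i])
    pk = spikes.peak_idx[i]
    # left crossing between threshold and peak
    left = None
    for j in range(pk, spikes.threshold_idx[i], -1):
        if v[j - 1] < half <= v[j]:
            frac = (half - v[j - 1]) / (v[j] - v[j - 1])
            left = (j - 1 + frac) * dt
            break
    stop = spikes.trough_idx[i] + 1
    right = None
    for j in range(pk, stop):
        if j + 1 >= v.size:
            break
        if v[j] >= half > v[j + 1]:
            frac = (v[j] - half) / (v[j] - v[j + 1])
            right = (j + frac) * dt
            break
    if left is None or right is None:
        return float("nan")
    return float((right - left) * 1000.0)


def _first_spiking_sweep(
    sweep_set: SweepSet,
    protocol: StimulusProtocol,
    spikes: dict[int, DetectedSpikes],
) -> int | None:
    """Index of the lowest depolarizing sweep with >=1 in-window AP."""
    for i, s in enumerate(sweep_set.sweeps):
        if s.current_pA > 0 and spikes[i].n_in_window() >= 1:
            return i
    return None


def ap_shape_features(
    sweep_set: SweepSet,
    protocol: StimulusProtocol,
    spikes: dict[int, DetectedSpikes],
) -> dict[str, float]:
    """Shape of the first AP fired: threshold, amplitude, width, AHP, ADP,
    latency, upstroke/downstroke ratio, plus latency at rheobase + 20 pA."""
    out = {k: float("nan") for k in (
        "AP_threshold", "AP_amplitude", "AP_width", "AHP", "ADP",
        "latency", "latency_rheo_plus20", "UDR")}
    idx = _first_spiking_sweep(sweep_set, protocol, spikes)
    if idx is None:
        return out
    sweep = sweep_set.sweeps[idx]
    sp = spikes[idx]
    first = int(np.nonzero(sp.in_window())[0][0])
    dt = sweep.sample_period_s
    dvdt = np.gradient(sweep.voltage_mV, dt) / 1000.0
    thr_i, pk_i, tr_i = sp.threshold_idx[first], sp.peak_idx[first], sp.trough_idx[first]
    out["AP_threshold"] = float(sp.threshold_v[first])
    out["AP_amplitude"] = float(sp.peak_v[first] - sp.threshold_v[first])
    out["AP_width"] = _half_width_ms(sweep, sp, first)
    out["AHP"] = float(sp.threshold_v[first] - sp.trough_v[first])
    out["ADP"] = float(sp.adp_mV[first])
    out["latency"] = float((sp.threshold_t[first] - protocol.onset_s) * 1000.0)
    up = float(np.max(dvdt[thr_i:pk_i + 1]))
    down = float(np.max(np.abs(dvdt[pk_i:tr_i + 1])))
    out["UDR"] = up / down if down > 0 else float("nan")

    target = sweep.current_pA + 20.0
    for j, s in enumerate(sweep_set.sweeps):
        if abs(s.current_pA - target) < 1e-6 and spikes[j].n_in_window() >= 1:
            k = int(np.nonzero(spikes[j].in_window())[0][0])
            out["latency_rheo_plus20"] = float(
                (spikes[j].threshold_t[k] - protocol.onset_s) * 1000.0)
            break
    return out


# --------------------------------------------------------------------------
# Adaptation indices
# --------------------------------------------------------------------------

def _ratio_indices(values: np.ndarray) -> tuple[float, float]:
    """(second/first, mean of consecutive ratios) for a sequence of >=2 values."""
    ratios = values[1:] / values[:-1]
    return float(ratios[0]), float(np.mean(ratios))


def adaptation_features(
    sweep_set: SweepSet,
    protocol: StimulusProtocol,
    spikes: dict[int, DetectedSpikes],
) -> dict[str, float]:
    """ISI and AP-amplitude adaptation indices.

    ISI adaptation is the ratio of the second to the first ISI (and the mean
    of all consecutive-ISI ratios); amplitude indices are analogous on AP
    amplitudes.  Each is the median over the five lowest depolarizing
    currents with enough spikes (>=3 for ISI, >=2 for amplitude).
    """
    firsts = sweep_set.first_repeats(sweep_set.depolarizing())
    index_of = {id(s): i for i, s in enumerate(sweep_set.sweeps)}
    isi_a, isi_avg, amp_a, amp_avg = [], [], [], []
    for s in firsts:
        sp = spikes[index_of[id(s)]]
        isis = sp.window_isis_s()
        amps = sp.window_amplitudes()
        if isis.size >= 2 and len(isi_a) < 5:
            a, b = _ratio_indices(isis)
            isi_a.append(a)
            isi_avg.append(b)
        if amps.size >= 2 and len(amp_a) < 5:
            a, b = _ratio_indices(amps)
            amp_a.append(a)
            amp_avg.append(b)
    nan = float("nan")
    return {
        "ISI_adaptation": float(np.median(isi_a)) if isi_a else nan,
        "ISI_avg_adaptation": float(np.median(isi_avg)) if isi_avg else nan,
        "AP_amp_adaptation": float(np.median(amp_a)) if amp_a else nan,
        "AP_amp_avg_adaptation": float(np.median(amp_avg)) if amp_avg else nan,
    }


# --------------------------------------------------------------------------
# Highest firing trace and firing statistics
# --------------------------------------------------------------------------

def select_highest_firing_trace(
    sweep_set: SweepSet,
    protocol: StimulusProtocol,
    spikes: dict[int, DetectedSpikes],
) -> int | None:
    """Index of the clean highest-firing depolarizing sweep.

    Sweeps with any AP in the 100 ms before or 200 ms after the stimulation
    window are excluded first; among the rest the first (lowest current,
    lowest repeat) sweep attaining the maximum in-window count wins.
    """
    best: int | None = None
    best_count = 0
    for i, s in enumerate(sweep_set.sweeps):
        if s.current_pA <= 0:
            continue
        sp = spikes[i]
        if sp.n_pre_window() > 0 or sp.n_post_window() > 0:
            continue
        c = sp.n_in_window()
        if c > best_count:
            best, best_count = i, c
    if best_count == 0:
        return None
    return best


def isi_coefficient_of_variation(isis: np.ndarray) -> float:
    """std/mean of interspike intervals (population std); NaN with <2 ISIs.

    A homogeneous Poisson spike train has ISI CV = 1.
    """
    isis = np.asarray(isis, dtype=float)
    if isis.size < 2 or np.mean(isis) == 0:
        return float("nan")
    return float(np.std(isis) / np.mean(isis))


def _fano(values: np.ndarray) -> float:
    if values.size < 2 or np.mean(values) == 0:
        return float("nan")
    return float(np.var(values) / np.mean(values))


def firing_statistics(
    sweep_set: SweepSet,
    protocol: StimulusProtocol,
    spikes: dict[int, DetectedSpikes],
    highest_idx: int | None,
) -> dict[str, float]:
    """Statistics of the highest firing trace: max AP count, spike-frequency
    adaptation (second-half / first-half counts, needs >=5 APs), and
    CV / Fano factors of the ISIs and AP amplitudes."""
    nan = float("nan")
    out = {"max_num_APs": nan, "SFA": nan, "ISI_CV": nan, "ISI_Fano": nan,
           "AP_CV": nan, "AP_Fano": nan}
    if highest_idx is None:
        return out
    sp = spikes[highest_idx]
    mask = sp.in_window()
    t = sp.threshold_t[mask]
    amps = sp.amplitudes_mV[mask]
    out["max_num_APs"] = float(t.size)
    mid = protocol.onset_s + protocol.duration_s / 2.0
    if t.size >= 5:
        n1 = int(np.count_nonzero(t < mid))
        n2 = int(t.size - n1)
        out["SFA"] = float(n2 / n1) if n1 > 0 else nan
    isis = np.diff(t)
    out["ISI_CV"] = isi_coefficient_of_variation(isis)
    out["ISI_Fano"] = _fano(isis * 1000.0)
    if amps.size >= 2 and np.mean(amps) != 0:
        out["AP_CV"] = float(np.std(amps) / np.mean(amps))
        out["AP_Fano"] = _fano(amps)
    return out


# --------------------------------------------------------------------------
# Sag and rebound (lowest hyperpolarizing sweep)
# --------------------------------------------------------------------------

def _lowest_hyperpolarizing(sweep_set: SweepSet) -> Sweep | None:
    hyper = sweep_set.hyperpolarizing()
    if not hyper:
        return None
    cmin = min(s.current_pA for s in hyper)
    cands = [s for s in hyper if s.current_pA == cmin]
    return min(cands, key=lambda s: s.repeat_index)


def sag_features(
    sweep_set: SweepSet, protocol: StimulusProtocol
) -> tuple[float, float, float]:
    """(sag_ratio, sag_time [ms], sag_area [mV*ms]) from the lowest
    hyperpolarizing sweep.

    Sag ratio = (trough - rest) / (steady - rest), with the trough voltage
    averaged over a 5-ms window.  Sag time spans the first and second
    steady-state crossings after onset; sag area is |integral of
    (V - steady)| over that span.  If trough and steady state differ by less
    than 4 mV, sag time and area are exactly zero.
    """
    s = _lowest_hyperpolarizing(sweep_set)
    nan = float("nan")
    if s is None:
        return nan, nan, nan
    dt = s.sample_period_s
    v = s.voltage_mV
    v_rest = _resting_potential(s, protocol)
    ss = _steady_state(s, protocol)
    i_on = int(round(protocol.onset_s / dt))
    i_off = int(round(protocol.offset_s / dt))
    seg = v[i_on:i_off]
    minima = np.nonzero(seg == seg.min())[0]
    tr = int(minima[minima.size // 2])  # centre of a flat trough
    half_w = max(int(round(0.0025 / dt)), 1)
    lo = max(tr - half_w, 0)
    hi = min(tr + half_w + 1, seg.size)
    trough_v = float(np.mean(seg[lo:hi]))
    denom = ss - v_rest
    ratio = (trough_v - v_rest) / denom if denom != 0 else nan
    if abs(trough_v - ss) < 4.0:
        return float(ratio), 0.0, 0.0
    below = seg < ss
    cross = np.nonzero(np.diff(below.astype(int)) != 0)[0]
    if cross.size < 2:
        return float(ratio), 0.0, 0.0
    a, b = int(cross[0]) + 1, int(cross[1]) + 1
    sag_time = (b - a) * dt * 1000.0
    sag_area = abs(float(np.trapezoid(seg[a:b] - ss, dx=dt))) * 1000.0
    return float(ratio), float(sag_time), float(sag_area)


def rebound_features(
    sweep_set: SweepSet,
    protocol: StimulusProtocol,
    spikes: dict[int, DetectedSpikes],
    v_rest: float,
) -> tuple[float, float]:
    """(rebound [mV], rebound AP count) after the lowest hyperpolarizing pulse.

    Rebound onset is the first post-offset sample at which V reaches the
    resting potential; the rebound is the mean voltage above rest over the
    following 150 ms (truncated at 300 ms post-offset).  If V never reaches
    rest within 300 ms the rebound is exactly zero.
    """
    s = _lowest_hyperpolarizing(sweep_set)
    if s is None:
        return float("nan"), float("nan")
    dt = s.sample_period_s
    v = s.voltage_mV
    i_off = int(round(protocol.offset_s / dt))
    i_lim = min(int(round((protocol.offset_s + 0.3) / dt)), v.size)
    post = v[i_off:i_lim]
    reached = np.nonzero(post >= v_rest)[0]
    if reached.size == 0:
        return 0.0, 0.0
    i_reb = i_off + int(reached[0])
    t_reb = i_reb * dt
    win = min(0.150, protocol.offset_s + 0.3 - t_reb)
    i_end = min(i_reb + int(round(win / dt)), v.size)
    rebound = float(np.mean(v[i_reb:i_end]) - v_rest)
    idx = sweep_set.sweeps.index(s)
    sp = spikes[idx]
    n_aps = int(np.count_nonzero(
        (sp.threshold_t >= t_reb) & (sp.threshold_t <= t_reb + win)))
    return rebound, float(n_aps)


# --------------------------------------------------------------------------
# Burstiness
# --------------------------------------------------------------------------

def classify_isis(
    isis_s: np.ndarray,
    adp_mV: np.ndarray,
    drawdown_mV: np.ndarray,
    pause_factor: float = 3.0,
    drop_mV: float = 0.5,
) -> list[str]:
    """Label each ISI 'detour', 'direct' or 'pauselike'.

    A detour ISI follows an AP with non-zero ADP or shows a voltage drop of
    at least ``drop_mV`` between the AP trough and the next threshold; a
    pauselike ISI is longer than ``pause_factor`` times the trace median ISI.
    """
    labels = []
    med = float(np.median(isis_s)) if isis_s.size else 0.0
    for i in range(isis_s.size):
        if med > 0 and isis_s[i] > pause_factor * med:
            labels.append("pauselike")
        elif adp_mV[i] > 0 or drawdown_mV[i] >= drop_mV:
            labels.append("detour")
        else:
            labels.append("direct")
    return labels


def detect_bursts(labels: Sequence[str]) -> list[tuple[int, int]]:
    """Burst spans [onset, offset] over ISI indices.

    A burst onset is a detour ISI followed by a direct ISI; the burst runs
    through the consecutive direct ISIs and ends when a direct ISI is
    followed by a detour (or the train ends).  Bursts containing a pauselike
    ISI are discarded.
    """
    bursts = []
    i = 0
    n = len(labels)
    while i < n - 1:
        if labels[i] == "detour" and labels[i + 1] == "direct":
            j = i + 1
            while j + 1 < n and labels[j + 1] == "direct":
                j += 1
            if all(labels[k] != "pauselike" for k in range(i, j + 1)):
                bursts.append((i, j))
            i = j + 1
        else:
            i += 1
    return bursts


def burstiness(
    sweep_set: SweepSet,
    protocol: StimulusProtocol,
    spikes: dict[int, DetectedSpikes],
    n_traces: int = 5,
    pause_factor: float = 3.0,
) -> float:
    """Burstiness in [-1, 1]: contrast between the fastest intra-burst and
    fastest extra-burst instantaneous rates, median over the first five
    depolarizing traces; 0 when no burst is detected."""
    firsts = sweep_set.first_repeats(sweep_set.depolarizing())[:n_traces]
    index_of = {id(s): i for i, s in enumerate(sweep_set.sweeps)}
    values = []
    for s in firsts:
        sp = spikes[index_of[id(s)]]
        mask = sp.in_window()
        t = sp.threshold_t[mask]
        if t.size < 3:
            values.append(0.0)
            continue
        isis = np.diff(t)
        pos = np.nonzero(mask)[0]
        adp = sp.adp_mV[pos[:-1]]
        dd = np.array([
            sp.isi_drawdown_mV[k] if k < sp.isi_drawdown_mV.size else 0.0
            for k in pos[:-1]
        ])
        labels = classify_isis(isis, adp, dd, pause_factor=pause_factor)
        bursts = detect_bursts(labels)
        if not bursts:
            values.append(0.0)
            continue
        in_burst = np.zeros(isis.size, dtype=bool)
        for a, b in bursts:
            in_burst[a:b + 1] = True
        if in_burst.all() or not in_burst.any():
            values.append(0.0)
            continue
        f_in = 1.0 / float(np.min(isis[in_burst]))
        f_out = 1.0 / float(np.min(isis[~in_burst]))
        values.append((f_in - f_out) / (f_in + f_out))
    return float(np.median(values)) if values else 0.0


def wildness(
    sweep_set: SweepSet,
    protocol: StimulusProtocol,
    spikes: dict[int, DetectedSpikes],
    highest_idx: int | None,
) -> float:
    """Excess in-window APs of the overall highest-firing sweep (possibly
    firing outside the stimulation window) over the clean highest-firing
    sweep; 0 when no sweep fires out of window."""
    counts = [spikes[i].n_in_window()
              for i, s in enumerate(sweep_set.sweeps) if s.current_pA > 0]
    if not counts:
        return float("nan")
    overall = max(counts)
    clean = spikes[highest_idx].n_in_window() if highest_idx is not None else 0
    return float(max(overall - clean, 0))


# --------------------------------------------------------------------------
# Full 29-feature record and 17-feature analysis vector
# --------------------------------------------------------------------------

@dataclass
class EphysFeatures:
    """The 29 extracted electrophysiological features (NaN = undefined)."""

    resting_potential: float = float("nan")
    input_resistance: float = float("nan")
    rheobase: float = float("nan")
    AP_threshold: float = float("nan")
    AP_amplitude: float = float("nan")
    AP_width: float = float("nan")
    AHP: float = float("nan")
    ADP: float = float("nan")
    latency: float = float("nan")
    latency_rheo_plus20: float = float("nan")
    UDR: float = float("nan")
    ISI_adaptation: float = float("nan")
    ISI_avg_adaptation: float = float("nan")
    AP_amp_adaptation: float = float("nan")
    AP_amp_avg_adaptation: float = float("nan")
    max_num_APs: float = float("nan")
    SFA: float = float("nan")
    membrane_tau: float = float("nan")
    sag_ratio: float = float("nan")
    sag_time: float = float("nan")
    sag_area: float = float("nan")
    rebound: float = float("nan")
    rebound_num_APs: float = float("nan")
    ISI_CV: float = float("nan")
    ISI_Fano: float = float("nan")
    AP_CV: float = float("nan")
    AP_Fano: float = float("nan")
    burstiness: float = float("nan")
    wildness: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: The 17 features retained for statistical analysis (the other 12 are mostly
#: zero, highly redundant, heavily skewed, or undefined for some cells).
ANALYSIS_FEATURES: tuple[str, ...] = (
    "resting_potential", "input_resistance", "rheobase", "AP_threshold",
    "AP_amplitude", "AP_width", "AHP", "latency", "UDR", "ISI_adaptation",
    "AP_amp_adaptation", "max_num_APs", "membrane_tau", "sag_ratio",
    "rebound", "ISI_CV", "AP_CV",
)

#: Features log-transformed to make their distributions more Gaussian-like.
LOG_TRANSFORMED_FEATURES: tuple[str, ...] = (
    "AP_CV", "ISI_CV", "ISI_adaptation", "latency",
)


def assemble_analysis_vector(features: EphysFeatures) -> tuple[np.ndarray, bool]:
    """17-feature analysis vector with the four named features log-transformed.

    Returns (vector, complete); cells with any missing retained feature are
    flagged incomplete and should be excluded from analyses requiring full
    vectors.
    """
    vec = np.empty(len(ANALYSIS_FEATURES))
    complete = True
    for i, name in enumerate(ANALYSIS_FEATURES):
        val = getattr(features, name)
        if name in LOG_TRANSFORMED_FEATURES:
            val = math.log(val) if val > 0 else float("nan")
        vec[i] = val
        if not np.isfinite(vec[i]):
            complete = False
    return vec, complete


def extract_features(
    sweep_set: SweepSet,
    protocol: StimulusProtocol,
    params: SpikeDetectionParams | None = None,
) -> EphysFeatures:
    """Run the full feature-extraction cascade on one cell's sweep set."""
    spikes = {i: detect_spikes(s, protocol, params)
              for i, s in enumerate(sweep_set.sweeps)}
    f = EphysFeatures()
    f.resting_potential, f.input_resistance, f.membrane_tau = passive_features(
        sweep_set, protocol)

    counts = {}
    for s in sweep_set.first_repeats(sweep_set.depolarizing()):
        idx = sweep_set.sweeps.index(s)
        counts[s.current_pA] = spikes[idx].n_in_window()
    f.rheobase = rheobase(counts)

    for k, v in ap_shape_features(sweep_set, protocol, spikes).items():
        setattr(f, k, v)
    for k, v in adaptation_features(sweep_set, protocol, spikes).items():
        setattr(f, k, v)

    hi = select_highest_firing_trace(sweep_set, protocol, spikes)
    for k, v in firing_statistics(sweep_set, protocol, spikes, hi).items():
        setattr(f, k, v)

    f.sag_ratio, f.sag_time, f.sag_area = sag_features(sweep_set, protocol)
    f.rebound, f.rebound_num_APs = rebound_features(
        sweep_set, protocol, spikes, f.resting_potential)
    f.burstiness = burstiness(sweep_set, protocol, spikes)
    f.wildness = wildness(sweep_set, protocol, spikes, hi)
    return f


# --------------------------------------------------------------------------
# Sweep-set I/O
# --------------------------------------------------------------------------

def write_sweep_set_h5(sweep_set: SweepSet, path) -> None:
    """Store a sweep set in HDF5: one dataset per sweep with stimulus
    metadata (current_pA, repeat_index, sample_period_s) as attributes."""
    import h5py

    with h5py.File(path, "w") as fh:
        for i, s in enumerate(sweep_set.sweeps):
            d = fh.create_dataset(f"sweep_{i:04d}", data=s.voltage_mV)
            d.attrs["current_pA"] = s.current_pA
            d.attrs["repeat_index"] = s.repeat_index
            d.attrs["sample_period_s"] = s.sample_period_s


def read_sweep_set_h5(path) -> SweepSet:
    import h5py

    sweeps = []
    with h5py.File(path, "r") as fh:
        for key in sorted(fh):
            d = fh[key]
            sweeps.append(Sweep(
                sample_period_s=float(d.attrs["sample_period_s"]),
                voltage_mV=d[()],
                current_pA=float(d.attrs["current_pA"]),
                repeat_index=int(d.attrs["repeat_index"])))
    return SweepSet(sweeps)


def write_sweep_table_csv(sweep_set: SweepSet, path) -> None:
    """Long-format CSV sweep table with documented columns:
    sweep, current_pA, repeat_index, sample_period_s, sample, voltage_mV."""
    import pandas as pd

    frames = []
    for i, s in enumerate(sweep_set.sweeps):
        frames.append(pd.DataFrame({
            "sweep": i, "current_pA": s.current_pA,
            "repeat_index": s.repeat_index,
            "sample_period_s": s.sample_period_s,
            "sample": np.arange(s.voltage_mV.size),
            "voltage_mV": s.voltage_mV}))
    pd.concat(frames).to_csv(path, index=False)


def read_sweep_table_csv(path) -> SweepSet:
    import pandas as pd

    df = pd.read_csv(path)
    sweeps = []
    for _, g in df.groupby("sweep"):
        g = g.sort_values("sample")
        sweeps.append(Sweep(
            sample_period_s=float(g["sample_period_s"].iloc[0]),
            voltage_mV=g["voltage_mV"].to_numpy(),
            current_pA=float(g["current_pA"].iloc[0]),
            repeat_index=int(g["repeat_index"].iloc[0])))
    return SweepSet(sweeps)
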