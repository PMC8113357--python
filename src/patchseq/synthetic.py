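"""Synthetic Patch-seq data with known ground truth.

Three generators emulate the study's three modalities so that every
downstream stage can be scored against planted truth without any downloads:

* current-clamp sweep sets -- a passive double-exponential membrane response
  (charging + sag + rebound) with stereotyped analytic AP waveforms inserted
  at planted spike times and additive Gaussian noise;
* expression bundles -- negative-binomial UMI atlases around planted t-type
  centroids, with query cells drawn from the same centroids and counts split
  into exonic/intronic parts;
* SWC morphologies -- connected trees whose depth profile matches a planted
  20-bin histogram.

Everything is deterministic given the spec seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ephys import StimulusProtocol, Sweep, SweepSet
from .transcriptomics import ExpressionBundle, ReferenceAtlas
from .morphology import Morphology

__all__ = [
    "APShape",
    "TraceSpec",
    "SweepSetTruth",
    "generate_sweep_set",
    "AtlasSpec",
    "generate_expression_bundle",
    "MorphSpec",
    "generate_morphology",
    "poisson_spike_train",
]


# --------------------------------------------------------------------------
# Electrophysiology
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class APShape:
    """Analytic AP template: linear upstroke at the stated dV/dt, optional
    flat cap sized so the half-width is exact, exponential downstroke whose
    initial rate is the stated downstroke dV/dt, AHP trough, optional ADP
    bump, exponential return to baseline."""

    threshold_mV: float = -42.0
    amplitude_mV: float = 60.0
    halfwidth_ms: float = 1.0
    ahp_mV: float = 12.0
    adp_mV: float = 0.0
    upstroke_Vps: float = 200.0
    downstroke_Vps: float = 80.0

    def __post_init__(self) -> None:
        if self.halfwidth_ms <= 0:
            raise ValueError("halfwidth must be positive")
        if self.amplitude_mV <= 0 or self.upstroke_Vps <= 0 or self.downstroke_Vps <= 0:
            raise ValueError("amplitude and stroke rates must be positive")
        _ = self.cap_ms  # raises when the half-width is unreachable

    # derived timing (ms); V/s == mV/ms
    @property
    def t_upstroke_ms(self) -> float:
        return self.amplitude_mV / self.upstroke_Vps

    @property
    def tau_down_ms(self) -> float:
        return (self.amplitude_mV + self.ahp_mV) / self.downstroke_Vps

    @property
    def cap_ms(self) -> float:
        a, ahp = self.amplitude_mV, self.ahp_mV
        t_half_up = 0.5 * a / self.upstroke_Vps
        t_half_down = self.tau_down_ms * math.log((a + ahp) / (0.5 * a + ahp))
        pad = self.halfwidth_ms - t_half_up - t_half_down
        if pad < 0:
            raise ValueError(
                "halfwidth is too small for the requested stroke rates")
        return pad


@dataclass
class TraceSpec:
    """Planted ground truth for one synthetic cell's recordings."""

    resting_potential_mV: float = -70.0
    input_resistance_MOhm: float = 150.0
    membrane_tau_ms: float = 20.0
    sag_amplitude_mV: float = 0.0   # trough depth below steady state, lowest sweep
    sag_tau_ms: float = 50.0        # time-to-trough of the sag excursion
    rebound_mV: float = 0.0         # rebound bump height above rest, lowest sweep
    rebound_tau_ms: float = 60.0
    spike_times_s: Mapping[float, Sequence[float]] = field(default_factory=dict)
    ap_shape: APShape = field(default_factory=APShape)
    noise_sd_mV: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.membrane_tau_ms <= 0:
            raise ValueError("membrane tau must be positive")
        if self.noise_sd_mV < 0:
            raise ValueError("noise sd must be non-negative")


@dataclass
class SweepSetTruth:
    """Planted values retained alongside a generated sweep set."""

    v_rest_mV: float
    r_input_MOhm: float
    tau_ms: float
    spike_counts_in_window: dict[float, int]
    spike_times_s: dict[float, np.ndarray]
    sag_trough_mV: float
    sag_steady_mV: float
    sag_ratio: float
    rebound_mV: float
    ap_shape: APShape


def _alpha_bump(t: np.ndarray, tau: float) -> np.ndarray:
    """Unit-peak alpha function (t/tau) * exp(1 - t/tau), zero for t < 0."""
    out = np.zeros_like(t)
    m = t > 0
    out[m] = (t[m] / tau) * np.exp(1.0 - t[m] / tau)
    return out


def _ap_template(dt_s: float, shape: APShape, baseline_end_mV: float) -> np.ndarray:
    """Sampled AP waveform starting at the threshold crossing."""
    dt = dt_s * 1000.0  # ms
    thr, a, ahp = shape.threshold_mV, shape.amplitude_mV, shape.ahp_mV
    peak = thr + a
    trough = thr - ahp
    t_up, cap, tau_d = shape.t_upstroke_ms, shape.cap_ms, shape.tau_down_ms
    t_decay = 8.0 * tau_d
    pieces = []
    t = np.arange(0.0, t_up, dt)
    pieces.append(thr + shape.upstroke_Vps * t)
    if cap > 0:
        pieces.append(np.full(max(int(round(cap / dt)), 1), peak))
    t = np.arange(0.0, t_decay, dt)
    pieces.append(trough + (peak - trough) * np.exp(-t / tau_d))
    if shape.adp_mV > 0:
        # cosine rise to the ADP peak, then decay toward baseline
        t = np.arange(0.0, 2.0, dt)
        pieces.append(trough + shape.adp_mV * 0.5 * (1 - np.cos(np.pi * t / 2.0)))
        start = trough + shape.adp_mV
    else:
        start = trough
    t = np.arange(0.0, 40.0, dt)
    pieces.append(baseline_end_mV + (start - baseline_end_mV) * np.exp(-t / 10.0))
    return np.concatenate(pieces)


def _passive_trace(
    t: np.ndarray,
    spec: TraceSpec,
    protocol: StimulusProtocol,
    current_pA: float,
    sag_scale: float,
    has_spikes: bool = False,
) -> np.ndarray:
    """Noiseless sub-threshold membrane response for one current step."""
    vr = spec.resting_potential_mV
    tau = spec.membrane_tau_ms / 1000.0
    dv = current_pA * spec.input_resistance_MOhm * 1e-3  # pA * MOhm -> mV
    if current_pA > 0 and has_spikes:
        # stylized spiking-sweep baseline: a fast rise to an inter-spike
        # plateau placed so the planted AHP trough (and ADP bump) stay the
        # local extrema of every AP
        shape = spec.ap_shape
        trough = shape.threshold_mV - shape.ahp_mV
        plateau = (trough + 0.5 * shape.adp_mV if shape.adp_mV > 0
                   else shape.threshold_mV - 5.0)
        dv = plateau - vr
        tau = min(tau, 0.002)
    elif current_pA > 0:
        # keep the depolarized plateau below AP threshold
        dv = min(dv, spec.ap_shape.threshold_mV - 5.0 - vr)
    v = np.full_like(t, vr)
    on, off = protocol.onset_s, protocol.offset_s
    stim = (t >= on) & (t < off)
    ts = t[stim] - on
    v[stim] = vr + dv * (1.0 - np.exp(-ts / tau))
    if current_pA < 0 and spec.sag_amplitude_mV > 0:
        v[stim] -= (spec.sag_amplitude_mV * sag_scale
                    * _alpha_bump(ts, spec.sag_tau_ms / 1000.0))
    post = t >= off
    v_off = vr + dv * (1.0 - math.exp(-(off - on) / tau))
    tp = t[post] - off
    v[post] = vr + (v_off - vr) * np.exp(-tp / tau)
    if current_pA < 0 and spec.rebound_mV != 0:
        v[post] += (spec.rebound_mV * sag_scale
                    * _alpha_bump(tp, spec.rebound_tau_ms / 1000.0))
    return v


def generate_sweep_set(
    spec: TraceSpec,
    protocol: StimulusProtocol | None = None,
    sample_period_s: float = 5e-5,
    n_repeats: int = 1,
    post_window_s: float = 0.5,
) -> tuple[SweepSet, SweepSetTruth]:
    """Generate a sweep set for one cell and its ground truth.

    Each current step produces a passive charging response (plus sag and
    rebound on hyperpolarizing steps, scaled linearly with current), with
    AP templates inserted at the planted spike times (the planted time is
    the threshold crossing) and Gaussian noise on top.  Sag and rebound
    truths are evaluated on the analytic noiseless trace of the lowest
    hyperpolarizing sweep.
    """
    protocol = protocol or StimulusProtocol()
    rng = np.random.default_rng(spec.seed)
    dt = sample_period_s
    duration = protocol.offset_s + post_window_s
    t = np.arange(0.0, duration, dt)
    currents = np.asarray(protocol.current_steps_pA, dtype=float)
    c_min = currents.min()
    ramp_n = max(int(round(0.002 / dt)), 1)

    for c, times in spec.spike_times_s.items():
        for ts in times:
            if not 0.0 <= ts < duration:
                raise ValueError(
                    f"spike time {ts} s outside trace duration {duration} s")

    sweeps: list[Sweep] = []
    truth_times: dict[float, np.ndarray] = {}
    for c in currents:
        sag_scale = c / c_min if c_min < 0 else 0.0
        times = np.sort(np.asarray(spec.spike_times_s.get(c, ()), dtype=float))
        base = _passive_trace(t, spec, protocol, c, sag_scale,
                              has_spikes=times.size > 0)
        v = base.copy()
        truth_times[c] = times
        for ts in times:
            i0 = int(round(ts / dt))
            tpl = _ap_template(dt, spec.ap_shape, base[min(i0, base.size - 1)])
            i1 = min(i0 + tpl.size, v.size)
            j0 = max(i0 - ramp_n, 0)
            v[j0:i0] = np.linspace(v[j0], spec.ap_shape.threshold_mV,
                                   i0 - j0, endpoint=False)
            v[i0:i1] = tpl[: i1 - i0]
        for r in range(n_repeats):
            noisy = v + rng.normal(0.0, spec.noise_sd_mV, v.size) \
                if spec.noise_sd_mV > 0 else v.copy()
            sweeps.append(Sweep(sample_period_s=dt, voltage_mV=noisy,
                                current_pA=float(c), repeat_index=r))

    # ground truth for sag/rebound from the analytic lowest hyperpolarizing trace
    nan = float("nan")
    sag_trough = sag_steady = sag_ratio = reb = nan
    if c_min < 0:
        base = _passive_trace(t, spec, protocol, c_min, 1.0)
        on_i = int(round(protocol.onset_s / dt))
        off_i = int(round(protocol.offset_s / dt))
        sag_steady = float(np.mean(base[off_i - int(round(0.1 / dt)):off_i]))
        sag_trough = float(np.min(base[on_i:off_i]))
        vr = spec.resting_potential_mV
        if sag_steady != vr:
            sag_ratio = (sag_trough - vr) / (sag_steady - vr)
        post = base[off_i:min(off_i + int(round(0.3 / dt)), base.size)]
        hit = np.nonzero(post >= vr)[0]
        if hit.size:
            t_reb = (off_i + hit[0]) * dt
            win = min(0.150, protocol.offset_s + 0.3 - t_reb)
            seg = base[off_i + hit[0]: off_i + hit[0] + int(round(win / dt))]
            reb = float(np.mean(seg) - vr)
        else:
            reb = 0.0

    counts = {
        c: int(np.count_nonzero(
            (truth_times[c] >= protocol.onset_s)
            & (truth_times[c] <= protocol.offset_s)))
        for c in truth_times
    }
    truth = SweepSetTruth(
        v_rest_mV=spec.resting_potential_mV,
        r_input_MOhm=spec.input_resistance_MOhm,
        tau_ms=spec.membrane_tau_ms,
        spike_counts_in_window=counts,
        spike_times_s=truth_times,
        sag_trough_mV=sag_trough,
        sag_steady_mV=sag_steady,
        sag_ratio=sag_ratio,
        rebound_mV=reb,
        ap_shape=spec.ap_shape,
    )
    return SweepSet(sweeps), truth


def poisson_spike_train(
    rate_hz: float, duration_s: float, seed: int, t_start: float = 0.0
) -> np.ndarray:
    """Homogeneous Poisson spike times on [t_start, t_start + duration)."""
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate_hz * duration_s)
    return t_start + np.sort(rng.uniform(0.0, duration_s, n))


# --------------------------------------------------------------------------
# Transcriptomics
# --------------------------------------------------------------------------

@dataclass
class AtlasSpec:
    """Planted reference-atlas model: t-type centroids in log2 space with
    negative-binomial count noise, per-cell library-size scaling and a
    binomial exon/intron split per gene."""

    n_types: int = 10
    n_genes: int = 2000
    n_cells_per_type: int = 50
    centroid_log_expression: np.ndarray | None = None  # types x genes, log2(mean+1)
    separation: float = 4.0         # marker elevation in log2 units
    markers_per_type: int = 30
    dispersion: float = 0.3         # NB inverse size; var = mu + dispersion * mu^2
    library_size_sigma: float = 0.25
    exon_fraction: np.ndarray | None = None
    family_of_type: dict[str, str] | None = None
    group_of_type: dict[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 2:
            raise ValueError("need at least 2 types")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    @property
    def type_names(self) -> list[str]:
        return [f"type_{i:03d}" for i in range(self.n_types)]

    def build_centroids(self) -> np.ndarray:
        """Planted centroid matrix (types x genes) in log2(mean count + 1)."""
        if self.centroid_log_expression is not None:
            c = np.asarray(self.centroid_log_expression, dtype=float)
            if c.shape != (self.n_types, self.n_genes):
                raise ValueError("centroid matrix shape mismatch")
            return c
        rng = np.random.default_rng(self.seed)
        base = np.clip(rng.normal(1.0, 0.8, self.n_genes), 0.0, None)
        cent = np.tile(base, (self.n_types, 1))
        for k in range(self.n_types):
            lo = k * self.markers_per_type % self.n_genes
            idx = (lo + np.arange(self.markers_per_type)) % self.n_genes
            cent[k, idx] += self.separation
        return cent

    def default_labels(self) -> tuple[dict[str, str], dict[str, str]]:
        groups = ["CGE", "MGE", "excitatory"]
        families = {"CGE": ["Vip", "Lamp5"], "MGE": ["Pvalb", "Sst"],
                    "excitatory": ["IT", "ET"]}
        fam, grp = {}, {}
        for i, name in enumerate(self.type_names):
            g = groups[i % 3]
            grp[name] = g
            fam[name] = families[g][(i // 3) % 2]
        return fam, grp


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def _sample_cells(
    rng: np.random.Generator,
    centroids: np.ndarray,
    type_idx: np.ndarray,
    dispersion: float,
    lib_sigma: float,
) -> np.ndarray:
    """Counts matrix (genes x cells) for cells of the given planted types."""
    mu = 2.0 ** centroids[type_idx] - 1.0  # cells x genes
    lib = np.exp(rng.normal(0.0, lib_sigma, type_idx.size))
    counts = _nb_counts(rng, np.clip(mu * lib[:, None], 1e-9, None), dispersion)
    return counts.T


def generate_expression_bundle(
    spec: AtlasSpec,
    n_query_cells: int = 100,
    query_noise: float = 1.0,
    n_atlases: int = 1,
) -> tuple[list[ReferenceAtlas], ExpressionBundle, np.ndarray]:
    """Reference atlas(es) plus a query bundle drawn from the same centroids.

    ``query_noise`` scales the query cells' NB dispersion; at 0 the query
    counts equal the rounded centroid means exactly.  Returns
    (atlases, query_bundle, true_type_labels).
    """
    rng = np.random.default_rng(spec.seed)
    centroids = spec.build_centroids()
    genes = np.array([f"gene_{i:05d}" for i in range(spec.n_genes)])
    fam, grp = (spec.family_of_type, spec.group_of_type)
    if fam is None or grp is None:
        d_fam, d_grp = spec.default_labels()
        fam = fam or d_fam
        grp = grp or d_grp

    atlases = []
    for _ in range(n_atlases):
        type_idx = np.repeat(np.arange(spec.n_types), spec.n_cells_per_type)
        counts = _sample_cells(rng, centroids, type_idx, spec.dispersion,
                               spec.library_size_sigma)
        atlases.append(ReferenceAtlas(
            genes=genes,
            counts=counts,
            cell_types=np.array(spec.type_names)[type_idx],
            type_names=list(spec.type_names),
            family_of_type=dict(fam),
            group_of_type=dict(grp),
            platform="UMI",
        ))

    true_idx = rng.integers(0, spec.n_types, n_query_cells)
    mu = 2.0 ** centroids[true_idx] - 1.0
    if query_noise == 0:
        q_counts = np.rint(mu).astype(np.int64).T
    else:
        q_counts = _nb_counts(
            rng, np.clip(mu, 1e-9, None), spec.dispersion * query_noise).T

    exon_frac = spec.exon_fraction
    if exon_frac is None:
        exon_frac = rng.uniform(0.3, 0.9, spec.n_genes)
    if np.any((exon_frac < 0) | (exon_frac > 1)):
        raise ValueError("exon fractions must lie in [0, 1]")
    if query_noise == 0:
        exon = np.rint(q_counts * exon_frac[:, None]).astype(np.int64)
    else:
        exon = rng.binomial(q_counts, exon_frac[:, None])
    intron = q_counts - exon
    bundle = ExpressionBundle(
        genes=genes,
        exon_counts=exon,
        intron_counts=intron,
        exonic_length_kb=rng.lognormal(0.5, 0.5, spec.n_genes),
        intronic_length_kb=rng.lognormal(1.5, 0.7, spec.n_genes),
        platform="read",
    )
    labels = np.array(spec.type_names)[true_idx]
    return atlases, bundle, labels


# --------------------------------------------------------------------------
# Morphology
# --------------------------------------------------------------------------

@dataclass
class CompartmentSpec:
    """Generation recipe for one neurite compartment.

    With ``planted_profile`` set, the compartment is built as a vertical
    trunk plus horizontal branchlets whose per-bin lengths realize the
    planted 20-bin depth histogram (up to the small trunk contribution).
    Otherwise a random branching tree is grown with the stated counts.
    """

    planted_profile: np.ndarray | None = None
    total_length_um: float = 3000.0
    n_stems: int = 2
    n_branch_points: int = 10
    segment_length_um: float = 60.0
    segment_length_sd_um: float = 15.0


@dataclass
class MorphSpec:
    soma_depth_normalized: float = 0.4
    cortical_thickness_um: float = 1000.0
    soma_radius_um: float = 8.0
    compartments: dict[str, CompartmentSpec] = field(
        default_factory=lambda: {"axon": CompartmentSpec(),
                                 "dendrite": CompartmentSpec()})
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.soma_depth_normalized <= 1.0:
            raise ValueError("soma depth must be normalized to [0, 1]")
        if self.cortical_thickness_um <= 0:
            raise ValueError("cortical thickness must be positive")


_SWC_TYPE = {"soma": 1, "axon": 2, "dendrite": 3}


def _planted_profile_nodes(
    cspec: CompartmentSpec,
    soma_z: float,
    thickness: float,
    swc_type: int,
    next_id: int,
    soma_id: int,
    x_sign: float,
) -> tuple[list[tuple], int]:
    """Trunk + horizontal branchlets realizing a planted depth histogram."""
    prof = np.asarray(cspec.planted_profile, dtype=float)
    prof = prof / prof.sum()
    n_bins = prof.size
    centers = (np.arange(n_bins) + 0.5) / n_bins * thickness
    active = np.nonzero(prof > 0)[0]
    zs = np.unique(np.concatenate([[soma_z], centers[active]]))
    rows: list[tuple] = []
    # vertical trunk through soma depth and all active bin centers
    trunk_id_at: dict[float, int] = {}
    prev_id = soma_id
    prev_z = soma_z
    order = np.concatenate([
        np.sort(zs[zs >= soma_z]),          # downward from soma
        np.sort(zs[zs < soma_z])[::-1],     # then upward from soma
    ])
    for z in order:
        if z == soma_z:
            trunk_id_at[z] = soma_id
            continue
        if (z >= soma_z) != (prev_z >= soma_z):
            prev_id, prev_z = soma_id, soma_z  # restart at soma for the up trunk
        rows.append((next_id, swc_type, 0.0, 0.0, z, 0.5, prev_id))
        trunk_id_at[z] = next_id
        prev_id, prev_z = next_id, z
        next_id += 1
    for b in active:
        length = prof[b] * cspec.total_length_um
        parent = trunk_id_at[centers[b]]
        rows.append((next_id, swc_type, x_sign * length, 0.0, centers[b], 0.5, parent))
        next_id += 1
    return rows, next_id


def _random_tree_nodes(
    rng: np.random.Generator,
    cspec: CompartmentSpec,
    soma_z: float,
    thickness: float,
    swc_type: int,
    next_id: int,
    soma_id: int,
) -> tuple[list[tuple], int]:
    rows: list[tuple] = []
    open_tips: list[tuple[int, np.ndarray]] = []
    for _ in range(max(cspec.n_stems, 1)):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        open_tips.append((soma_id, d))
    splits_left = cspec.n_branch_points
    segments = max(cspec.n_stems, 1) + 2 * cspec.n_branch_points
    pos_of = {soma_id: np.array([0.0, 0.0, soma_z])}
    made = 0
    while open_tips and made < segments:
        parent, d = open_tips.pop(0)
        length = max(rng.normal(cspec.segment_length_um, cspec.segment_length_sd_um), 1.0)
        d = d + rng.normal(scale=0.3, size=3)
        d /= np.linalg.norm(d)
        end = pos_of[parent] + d * length
        end[2] = float(np.clip(end[2], 0.0, thickness))
        rows.append((next_id, swc_type, end[0], end[1], end[2], 0.5, parent))
        pos_of[next_id] = end
        made += 1
        if splits_left > 0 and rng.random() < 0.5:
            splits_left -= 1
            for _ in range(2):
                open_tips.append((next_id, d))
        else:
            open_tips.append((next_id, d))
        next_id += 1
    return rows, next_id


def generate_morphology(spec: MorphSpec) -> Morphology:
    """Connected SWC tree rooted at the soma, in the pia-aligned frame
    (x soma-centred, z = 0 at pia, z = thickness at white matter)."""
    rng = np.random.default_rng(spec.seed)
    soma_z = spec.soma_depth_normalized * spec.cortical_thickness_um
    rows: list[tuple] = [(1, 1, 0.0, 0.0, soma_z, spec.soma_radius_um, -1)]
    next_id = 2
    for i, (name, cspec) in enumerate(sorted(spec.compartments.items())):
        swc_type = _SWC_TYPE.get(name, 3)
        if cspec.planted_profile is not None:
            new, next_id = _planted_profile_nodes(
                cspec, soma_z, spec.cortical_thickness_um, swc_type,
                next_id, 1, x_sign=1.0 if i % 2 == 0 else -1.0)
        else:
            new, next_id = _random_tree_nodes(
                rng, cspec, soma_z, spec.cortical_thickness_um, swc_type,
                next_id, 1)
        rows.extend(new)
    nodes = pd.DataFrame(
        rows, columns=["id", "type", "x", "y", "z", "radius", "parent"])
    return Morphology(nodes=nodes, cortical_thickness_um=spec.cortical_thickness_um)
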