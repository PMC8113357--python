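"""End-to-end orchestration of the multimodal analysis on synthetic data.

A single config drives generation of the three modalities (or any subset),
feature extraction, t-type mapping, representation building, kNN family
classification and the variability report.  All randomness derives from one
master seed fanned out to per-stage seeds through a spawned SeedSequence, so
a rerun with the same config is bit-identical.  Outputs land in a run
directory as tidy CSVs plus a provenance JSON.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ephys import (ANALYSIS_FEATURES, StimulusProtocol,
                    assemble_analysis_vector, extract_features)
from .embedding import build_ephys_representation, knn_family_classify
from .morphology import morphometrics, z_profile
from .synthetic import (APShape, AtlasSpec, CompartmentSpec, MorphSpec,
                        TraceSpec, generate_expression_bundle,
                        generate_morphology, generate_sweep_set)
from .transcriptomics import assign_ttypes
from .variability import kmeans_baseline, normalized_total_variance

logger = logging.getLogger("patchseq")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips through YAML."""

    seed: int = 0
    n_cells: int = 40
    n_types: int = 6
    n_genes: int = 1200
    n_atlases: int = 2
    n_boot: int = 25
    round1_genes: int = 300
    round2_genes: int = 150
    with_ephys: bool = True
    with_transcriptomics: bool = True
    with_morphology: bool = True
    protocol_onset_s: float = 0.1
    protocol_duration_s: float = 0.6
    current_steps_pA: list[float] = field(
        default_factory=lambda: [float(c) for c in range(-200, 401, 20)])
    exclude_cells: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _ephys_stage(cfg: PipelineConfig, seed: int, outdir: Path) -> pd.DataFrame:
    protocol = StimulusProtocol(
        onset_s=cfg.protocol_onset_s, duration_s=cfg.protocol_duration_s,
        current_steps_pA=tuple(cfg.current_steps_pA))
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(cfg.n_cells):
        r_in = float(rng.uniform(80, 250))
        rheo = 20.0 * int(rng.integers(3, 8))
        spikes = {}
        for cur in cfg.current_steps_pA:
            if cur >= rheo:
                n = min(int((cur - rheo) / 20) + 1, 12)
                spikes[cur] = list(protocol.onset_s + 0.01
                                   + np.linspace(0, 0.5, n))
        spec = TraceSpec(
            resting_potential_mV=float(rng.uniform(-75, -65)),
            input_resistance_MOhm=r_in,
            membrane_tau_ms=float(rng.uniform(10, 30)),
            sag_amplitude_mV=float(rng.uniform(0, 6)),
            rebound_mV=float(rng.uniform(0, 3)),
            spike_times_s=spikes,
            ap_shape=APShape(),
            noise_sd_mV=0.2,
            seed=int(rng.integers(2 ** 31)),
        )
        sweep_set, _ = generate_sweep_set(spec, protocol)
        feats = extract_features(sweep_set, protocol)
        row = feats.as_dict()
        vec, complete = assemble_analysis_vector(feats)
        row["cell"] = f"cell_{c:04d}"
        row["complete"] = complete
        rows.append(row)
    df = pd.DataFrame(rows).set_index("cell")
    df.to_csv(outdir / "ephys_features.csv")
    logger.info("ephys stage: %d cells, %d complete",
                len(df), int(df["complete"].sum()))
    return df


def _transcriptomic_stage(cfg: PipelineConfig, seed: int, outdir: Path):
    spec = AtlasSpec(n_types=cfg.n_types, n_genes=cfg.n_genes,
                     n_cells_per_type=30, seed=seed)
    atlases, bundle, true_labels = generate_expression_bundle(
        spec, n_query_cells=cfg.n_cells, n_atlases=cfg.n_atlases)
    assignment = assign_ttypes(
        bundle, atlases[0], atlases, n_boot=cfg.n_boot, seed=seed,
        round1_genes=cfg.round1_genes, round2_genes=cfg.round2_genes,
        exclude_cells=set(cfg.exclude_cells))
    table = assignment.table.copy()
    table["true_type"] = true_labels
    fam = atlases[0].family_of_type
    table["family"] = [fam.get(t) if t else None for t in table["final_type"]]
    table.to_csv(outdir / "assignments.csv", index=False)
    acc = float((table["final_type"] == table["true_type"])
                [table["qc_pass"]].mean())
    logger.info("mapping stage: accuracy %.3f on %d passing cells",
                acc, int(table["qc_pass"].sum()))
    return table


def _morphology_stage(cfg: PipelineConfig, seed: int, outdir: Path) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(cfg.n_cells):
        spec = MorphSpec(
            soma_depth_normalized=float(rng.uniform(0.1, 0.9)),
            compartments={
                "axon": CompartmentSpec(n_branch_points=8),
                "dendrite": CompartmentSpec(n_branch_points=6),
            },
            seed=int(rng.integers(2 ** 31)))
        morph = generate_morphology(spec)
        row = morphometrics(morph, "inhibitory")
        prof = z_profile(morph, "axon")
        row.update({f"zprofile_axon_{i:02d}": v for i, v in enumerate(prof)})
        row["cell"] = f"cell_{c:04d}"
        rows.append(row)
    df = pd.DataFrame(rows).set_index("cell")
    df.to_csv(outdir / "morphometrics.csv")
    logger.info("morphology stage: %d cells", len(df))
    return df


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run all configured stages; returns a result bundle of DataFrames.

    Stages whose modality is disabled are skipped gracefully; a stage
    failure raises with stage-scoped context.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    stage_seed = {name: int(s.generate_state(1)[0] % (2 ** 31))
                  for name, s in zip(("ephys", "transcriptomics", "morphology",
                                      "analysis"), ss.spawn(4))}
    results: dict = {}
    for name, enabled, fn in (
        ("ephys", config.with_ephys, _ephys_stage),
        ("transcriptomics", config.with_transcriptomics, _transcriptomic_stage),
        ("morphology", config.with_morphology, _morphology_stage),
    ):
        if not enabled:
            logger.info("stage %s skipped (modality absent)", name)
            continue
        try:
            results[name] = fn(config, stage_seed[name], outdir)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    if config.with_ephys and config.with_transcriptomics:
        ephys = results["ephys"]
        assign = results["transcriptomics"]
        complete = ephys[ephys["complete"]]
        merged = complete.join(
            assign.set_index("cell")[["final_type", "family", "qc_pass"]],
            how="inner")
        merged = merged[merged["qc_pass"].fillna(False)]
        if len(merged) >= 2 * len(ANALYSIS_FEATURES):
            from .ephys import EphysFeatures
            vecs = np.stack([
                assemble_analysis_vector(
                    EphysFeatures(**{k: row[k] for k in
                                     EphysFeatures().as_dict()}))[0]
                for _, row in merged.iterrows()])
            rep = build_ephys_representation(vecs)
            _, conf, fams = knn_family_classify(
                rep.matrix, merged["family"].to_numpy(),
                k=min(10, len(merged) - 1))
            pd.DataFrame(conf, index=fams, columns=fams).to_csv(
                outdir / "family_confusion.csv")
            var_rows = []
            types = merged["final_type"].to_numpy()
            qualifying = [t for t in pd.unique(types)
                          if np.count_nonzero(types == t) >= 2]
            for t in qualifying:
                var_rows.append(dict(ttype=t, n=int((types == t).sum()),
                                     normalized_total_variance=
                                     normalized_total_variance(vecs, types == t)))
            if len(qualifying) >= 2:
                lo, hi = kmeans_baseline(vecs, len(qualifying),
                                         stage_seed["analysis"])
                var_rows.append(dict(ttype="<kmeans_min>", n=len(vecs),
                                     normalized_total_variance=lo))
                var_rows.append(dict(ttype="<kmeans_max>", n=len(vecs),
                                     normalized_total_variance=hi))
            results["variability"] = pd.DataFrame(var_rows)
            results["variability"].to_csv(outdir / "variability.csv", index=False)

    provenance = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": asdict(config),
        "stage_seeds": stage_seed,
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    results["provenance"] = provenance
    return results
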