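"""Expression normalization, variable-gene selection and t-type mapping.

Query cells (read-based counts split into exonic and intronic parts) are
mapped onto reference atlases by Pearson correlation with per-t-type
centroid profiles.  Mapping runs in two rounds: round 1 assigns each cell to
one of three large transcriptomic groups (CGE, MGE, excitatory) and applies
quality control; round 2 maps each passing cell to the t-types of its group
in each reference atlas, with a gene bootstrap quantifying assignment
confidence, and the per-atlas confidences are averaged into a consensus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionBundle",
    "ReferenceAtlas",
    "GeneSelectionParams",
    "TypeAssignment",
    "normalize_expression",
    "select_variable_genes",
    "build_centroids",
    "map_cell",
    "round1_qc",
    "bootstrap_confidence",
    "consensus_assignment",
    "assign_ttypes",
]

_INTRON_LENGTH_GUARD = 1e-6


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class ExpressionBundle:
    """Query-cell expression: exon/intron counts (genes x cells) with gene
    lengths in kb, or UMI counts (platform='UMI', exon slot only)."""

    genes: np.ndarray
    exon_counts: np.ndarray
    intron_counts: np.ndarray | None = None
    exonic_length_kb: np.ndarray | None = None
    intronic_length_kb: np.ndarray | None = None
    platform: str = "read"
    cell_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes)
        self.exon_counts = np.asarray(self.exon_counts)
        if np.any(self.exon_counts < 0):
            raise ValueError("counts must be non-negative")
        if self.intron_counts is not None and np.any(np.asarray(self.intron_counts) < 0):
            raise ValueError("counts must be non-negative")
        if self.cell_ids is None:
            self.cell_ids = np.array(
                [f"cell_{i:04d}" for i in range(self.exon_counts.shape[1])])

    @property
    def n_cells(self) -> int:
        return self.exon_counts.shape[1]


@dataclass
class ReferenceAtlas:
    """Labelled reference: counts (genes x cells) with per-cell t-types,
    family/group per t-type and an optional non-neural flag per t-type."""

    genes: np.ndarray
    counts: np.ndarray
    cell_types: np.ndarray
    type_names: list[str]
    family_of_type: dict[str, str]
    group_of_type: dict[str, str]
    platform: str = "UMI"
    is_neural: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [t for t in self.type_names if t not in self.group_of_type]
        if missing:
            raise ValueError(f"types without a group: {missing[:5]}")

    def neural(self, t: str) -> bool:
        return self.is_neural.get(t, True)

    def log_expression(self) -> np.ndarray:
        """log2(count + 1) expression (genes x cells); UMI counts are used
        directly, without gene-length normalization."""
        return np.log2(self.counts + 1.0)


@dataclass(frozen=True)
class GeneSelectionParams:
    """Dropout-curve variable-gene selection parameters.

    ``c_min`` is the near-zero count ceiling (32 for read-based data, 0 for
    UMI data); genes with counts >= c_min in fewer than ``min_cells`` cells
    are excluded up front.  A gene is selected when its near-zero fraction
    tau exceeds exp(slope * mu + b) + margin, with the offset b found by
    binary search to hit ``target_n`` genes.
    """

    target_n: int = 500
    c_min: float = 32.0
    min_cells: int = 10
    slope: float = -1.5
    margin: float = 0.002

    @classmethod
    def for_platform(cls, platform: str, target_n: int) -> "GeneSelectionParams":
        return cls(target_n=target_n, c_min=0.0 if platform == "UMI" else 32.0)


# --------------------------------------------------------------------------
# Normalization
# --------------------------------------------------------------------------

def normalize_expression(bundle: ExpressionBundle) -> np.ndarray:
    """Gene-length-normalized log expression (genes x cells).

    Read-based data: log2(exon/len_exon + intron/(len_intron + 1e-6) + 1),
    lengths in kb.  UMI data passes through as log2(count + 1).
    """
    if bundle.platform == "UMI":
        return np.log2(bundle.exon_counts + 1.0)
    if bundle.exonic_length_kb is None or bundle.intronic_length_kb is None:
        raise ValueError("read-based data requires gene lengths")
    exon = bundle.exon_counts / np.asarray(bundle.exonic_length_kb)[:, None]
    intron = (np.asarray(bundle.intron_counts)
              / (np.asarray(bundle.intronic_length_kb) + _INTRON_LENGTH_GUARD)[:, None])
    return np.log2(exon + intron + 1.0)


# --------------------------------------------------------------------------
# Variable-gene selection
# --------------------------------------------------------------------------

def dropout_curve_stats(
    counts: np.ndarray, params: GeneSelectionParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(eligible mask, mu, tau) per gene.

    mu is the mean log2 count over counts strictly above c_min; tau is the
    fraction of counts <= c_min.  Genes failing the min-cells rule, or with
    no count above c_min, are ineligible (mu/tau = NaN).
    """
    counts = np.asarray(counts, dtype=float)
    above_eq = counts >= params.c_min
    above = counts > params.c_min
    eligible = above_eq.sum(axis=1) >= params.min_cells
    eligible &= above.any(axis=1)
    mu = np.full(counts.shape[0], np.nan)
    tau = np.full(counts.shape[0], np.nan)
    for g in np.nonzero(eligible)[0]:
        vals = counts[g, above[g]]
        mu[g] = np.mean(np.log2(vals))
        tau[g] = 1.0 - above[g].mean()
    return eligible, mu, tau


def _selection_mask(mu, tau, params: GeneSelectionParams, b: float) -> np.ndarray:
    with np.errstate(invalid="ignore", over="ignore"):
        return tau > np.exp(params.slope * mu + b) + params.margin


def select_variable_genes(
    counts: np.ndarray, params: GeneSelectionParams, n_iter: int = 200
) -> np.ndarray:
    """Indices of the most variable genes via the dropout-vs-mean curve.

    Binary search over the curve offset b targets exactly ``params.target_n``
    selected genes; if that count is unattainable (ties, or fewer eligible
    genes than requested) the nearest achievable selection is returned with
    a warning.
    """
    eligible, mu, tau = dropout_curve_stats(counts, params)
    n_eligible = int(np.count_nonzero(eligible & (tau > params.margin)))
    if n_eligible <= params.target_n:
        if n_eligible < params.target_n:
            warnings.warn(
                f"only {n_eligible} eligible genes for target "
                f"{params.target_n}; returning all of them")
        return np.nonzero(eligible & (tau > params.margin))[0]

    lo, hi = -50.0, 50.0
    best_mask = _selection_mask(mu, tau, params, lo)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        mask = _selection_mask(mu, tau, params, mid)
        n = int(np.count_nonzero(mask))
        if abs(n - params.target_n) < abs(int(best_mask.sum()) - params.target_n):
            best_mask = mask
        if n > params.target_n:
            lo = mid
        elif n < params.target_n:
            hi = mid
        else:
            best_mask = mask
            break
    n_final = int(best_mask.sum())
    if n_final != params.target_n:
        warnings.warn(
            f"binary search attained {n_final} genes for target {params.target_n}")
    return np.nonzero(best_mask)[0]


# --------------------------------------------------------------------------
# Centroids and mapping
# --------------------------------------------------------------------------

def build_centroids(
    log_expr: np.ndarray,
    cell_types: np.ndarray,
    type_names: list[str],
    gene_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Per-type mean log expression (types x genes)."""
    if gene_indices is not None:
        if len(gene_indices) == 0:
            raise ValueError("empty gene set")
        log_expr = log_expr[gene_indices]
    cents = np.full((len(type_names), log_expr.shape[0]), np.nan)
    for i, t in enumerate(type_names):
        m = cell_types == t
        if m.any():
            cents[i] = log_expr[:, m].mean(axis=1)
    return cents


def _pearson_to_rows(x: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Pearson correlation of vector x with each row of ``rows``."""
    xc = x - x.mean()
    rc = rows - rows.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xc)
    rn = np.linalg.norm(rc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rc @ xc) / (rn * xn)
    return r


def map_cell(
    cell_log_expr: np.ndarray, centroids: np.ndarray
) -> tuple[int, np.ndarray]:
    """(best type index, correlation vector) by Pearson correlation.

    Ties are broken by the first type in atlas order; a zero-variance cell
    vector is unmappable (index -1, NaN correlations).
    """
    if cell_log_expr.size < 3:
        raise ValueError("need at least 3 shared genes")
    if np.std(cell_log_expr) == 0:
        return -1, np.full(centroids.shape[0], np.nan)
    r = _pearson_to_rows(cell_log_expr, centroids)
    if not np.any(np.isfinite(r)):
        return -1, r
    return int(np.nanargmax(r)), r


@dataclass
class QCResult:
    passed: bool
    group: str | None
    best_type: str
    best_corr: float
    reason: str | None


def round1_qc(
    corrs: np.ndarray,
    type_names: list[str],
    group_of_type: dict[str, str],
    neural_of_type: dict[str, bool] | None = None,
    min_corr: float = 0.4,
    group_margin: float = 0.02,
) -> QCResult:
    """Round-1 quality control against a combined annotated atlas.

    A cell fails when its best correlation is below ``min_corr``, when it
    would be assigned to a non-neural t-type, or when the best correlation
    exceeds the best in one of the other two large groups by less than
    ``group_margin``.
    """
    best = int(np.nanargmax(corrs))
    best_t = type_names[best]
    best_r = float(corrs[best])
    if best_r < min_corr:
        return QCResult(False, None, best_t, best_r, "low_correlation")
    if neural_of_type is not None and not neural_of_type.get(best_t, True):
        return QCResult(False, None, best_t, best_r, "non_neural")
    group = group_of_type[best_t]
    others = [g for g in set(group_of_type.values()) if g != group]
    for g in others:
        idx = [i for i, t in enumerate(type_names) if group_of_type[t] == g]
        if idx and best_r - np.nanmax(corrs[idx]) < group_margin:
            return QCResult(False, None, best_t, best_r, "ambiguous_group")
    return QCResult(True, group, best_t, best_r, None)


def bootstrap_confidence(
    cell_log_expr: np.ndarray,
    centroids: np.ndarray,
    n_boot: int = 100,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Assignment confidence per type from a gene bootstrap.

    Genes are resampled with replacement at full set size; the fraction of
    draws in which the cell maps to each type is its confidence (sums to 1).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n_genes = cell_log_expr.size
    wins = np.zeros(centroids.shape[0])
    for _ in range(n_boot):
        idx = rng.integers(0, n_genes, n_genes)
        best, _ = map_cell(cell_log_expr[idx], centroids[:, idx])
        if best >= 0:
            wins[best] += 1
    total = wins.sum()
    return wins / total if total > 0 else wins


def consensus_assignment(
    confidences: list[np.ndarray], type_names: list[str]
) -> tuple[str, np.ndarray]:
    """Average per-atlas confidences and pick the argmax type (first type in
    atlas order on ties)."""
    if not confidences:
        raise ValueError("need at least one confidence vector")
    consensus = np.mean(np.stack(confidences), axis=0)
    return type_names[int(np.argmax(consensus))], consensus


# --------------------------------------------------------------------------
# End-to-end assignment
# --------------------------------------------------------------------------

@dataclass
class TypeAssignment:
    """Per-cell mapping result across the two rounds."""

    table: pd.DataFrame                      # one row per cell
    consensus: dict[str, np.ndarray]         # cell id -> consensus vector
    type_names_by_group: dict[str, list[str]]


def assign_ttypes(
    bundle: ExpressionBundle,
    combined_atlas: ReferenceAtlas,
    reference_atlases: list[ReferenceAtlas],
    n_boot: int = 100,
    seed: int = 0,
    round1_genes: int = 3000,
    round2_genes: int = 500,
    exclude_cells: set[str] | None = None,
) -> TypeAssignment:
    """Two-round t-type assignment with bootstrap consensus confidence.

    Round 1 maps every query cell to the combined atlas over its
    ``round1_genes`` most variable genes and applies QC; round 2 maps each
    passing cell, within its group, to every reference atlas over that
    atlas/group's ``round2_genes`` most variable genes, bootstrapping genes
    to obtain confidences that are averaged into the consensus.
    ``exclude_cells`` is a user-supplied curation list dropped at the end.
    """
    exclude_cells = exclude_cells or set()
    query_log = normalize_expression(bundle)

    # round 1: combined atlas, variable genes from its own counts
    p1 = GeneSelectionParams.for_platform(combined_atlas.platform, round1_genes)
    g1 = select_variable_genes(combined_atlas.counts, p1)
    shared1 = g1[np.isin(combined_atlas.genes[g1], bundle.genes)]
    ref_log = combined_atlas.log_expression()
    cents1 = build_centroids(ref_log, combined_atlas.cell_types,
                             combined_atlas.type_names, shared1)
    order = {g: i for i, g in enumerate(bundle.genes)}
    q_idx1 = np.array([order[g] for g in combined_atlas.genes[shared1]])

    # round 2 setup: per (atlas, group) centroids on that group's variable genes
    groups = sorted(set(combined_atlas.group_of_type.values()))
    atlas_group_maps = []
    for a_i, atlas in enumerate(reference_atlases):
        a_log = atlas.log_expression()
        per_group = {}
        for grp in groups:
            types = [t for t in atlas.type_names if atlas.group_of_type[t] == grp]
            cell_mask = np.isin(atlas.cell_types, types)
            if not cell_mask.any():
                continue
            p2 = GeneSelectionParams.for_platform(atlas.platform, round2_genes)
            g2 = select_variable_genes(atlas.counts[:, cell_mask], p2)
            shared2 = g2[np.isin(atlas.genes[g2], bundle.genes)]
            cents = build_centroids(a_log, atlas.cell_types, types, shared2)
            q_idx = np.array([order[g] for g in atlas.genes[shared2]])
            per_group[grp] = (types, cents, q_idx)
        atlas_group_maps.append(per_group)

    ss = np.random.SeedSequence(seed)
    cell_seeds = ss.generate_state(bundle.n_cells)

    rows = []
    consensus_store: dict[str, np.ndarray] = {}
    type_names_by_group: dict[str, list[str]] = {}
    for c in range(bundle.n_cells):
        cid = str(bundle.cell_ids[c])
        best1, corrs1 = map_cell(query_log[q_idx1, c], cents1)
        if best1 < 0:
            rows.append(dict(cell=cid, qc_pass=False, qc_reason="unmappable",
                             round1_group=None, round1_best_corr=np.nan,
                             final_type=None, consensus_confidence=np.nan))
            continue
        qc = round1_qc(corrs1, combined_atlas.type_names,
                       combined_atlas.group_of_type,
                       {t: combined_atlas.neural(t)
                        for t in combined_atlas.type_names})
        if not qc.passed or cid in exclude_cells:
            reason = qc.reason if not qc.passed else "excluded_by_list"
            rows.append(dict(cell=cid, qc_pass=False, qc_reason=reason,
                             round1_group=qc.group, round1_best_corr=qc.best_corr,
                             final_type=None, consensus_confidence=np.nan))
            continue
        grp = qc.group
        confs, types_ref = [], None
        rng = np.random.default_rng(cell_seeds[c])
        for per_group in atlas_group_maps:
            if grp not in per_group:
                continue
            types, cents, q_idx = per_group[grp]
            if types_ref is None:
                types_ref = types
            conf = bootstrap_confidence(query_log[q_idx, c], cents, n_boot, rng)
            confs.append(conf)
        if not confs:
            rows.append(dict(cell=cid, qc_pass=False, qc_reason="no_reference",
                             round1_group=grp, round1_best_corr=qc.best_corr,
                             final_type=None, consensus_confidence=np.nan))
            continue
        final, consensus = consensus_assignment(confs, types_ref)
        type_names_by_group[grp] = types_ref
        consensus_store[cid] = consensus
        rows.append(dict(cell=cid, qc_pass=True, qc_reason=None,
                         round1_group=grp, round1_best_corr=qc.best_corr,
                         final_type=final,
                         consensus_confidence=float(np.max(consensus))))
    return TypeAssignment(
        table=pd.DataFrame(rows), consensus=consensus_store,
        type_names_by_group=type_names_by_group)


# --------------------------------------------------------------------------
# Counts I/O (MTX + TSV)
# --------------------------------------------------------------------------

def write_expression_bundle(bundle: ExpressionBundle, directory) -> None:
    """Write a query bundle as MatrixMarket counts plus gene/cell TSVs."""
    import os

    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    os.makedirs(directory, exist_ok=True)
    mmwrite(os.path.join(directory, "exon_counts.mtx"),
            csr_matrix(bundle.exon_counts))
    if bundle.intron_counts is not None:
        mmwrite(os.path.join(directory, "intron_counts.mtx"),
                csr_matrix(bundle.intron_counts))
    genes = pd.DataFrame({"gene": bundle.genes})
    if bundle.exonic_length_kb is not None:
        genes["exonic_length_kb"] = bundle.exonic_length_kb
        genes["intronic_length_kb"] = bundle.intronic_length_kb
    genes.to_csv(os.path.join(directory, "genes.tsv"), sep="\t", index=False)
    pd.DataFrame({"cell": bundle.cell_ids}).to_csv(
        os.path.join(directory, "cells.tsv"), sep="\t", index=False)
    with open(os.path.join(directory, "platform.txt"), "w") as fh:
        fh.write(bundle.platform + "\n")


def read_expression_bundle(directory) -> ExpressionBundle:
    import os

    from scipy.io import mmread

    exon = np.asarray(mmread(os.path.join(directory, "exon_counts.mtx"))
                      .todense())
    intron_path = os.path.join(directory, "intron_counts.mtx")
    intron = (np.asarray(mmread(intron_path).todense())
              if os.path.exists(intron_path) else None)
    genes = pd.read_csv(os.path.join(directory, "genes.tsv"), sep="\t")
    cells = pd.read_csv(os.path.join(directory, "cells.tsv"), sep="\t")
    with open(os.path.join(directory, "platform.txt")) as fh:
        platform = fh.read().strip()
    return ExpressionBundle(
        genes=genes["gene"].to_numpy(),
        exon_counts=exon.astype(np.int64),
        intron_counts=None if intron is None else intron.astype(np.int64),
        exonic_length_kb=(genes["exonic_length_kb"].to_numpy()
                          if "exonic_length_kb" in genes else None),
        intronic_length_kb=(genes["intronic_length_kb"].to_numpy()
                            if "intronic_length_kb" in genes else None),
        platform=platform,
        cell_ids=cells["cell"].to_numpy())
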