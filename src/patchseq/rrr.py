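"""Sparse reduced-rank regression (RRR) of phenotype on gene expression.

The model predicts the standardized electrophysiological feature matrix Y
(n x q) from standardized log-expression X (n x p) through a rank-r
bottleneck, Y ~ X W V', with an elastic-net penalty on the rows of the gene
weight matrix W so that only a small set of genes gets nonzero weight
(l1_ratio alpha = 1 is pure lasso).  Fitting alternates between a
row-sparse multi-task elastic-net regression of Y V on X (W-step) and an
orthogonal Procrustes update of V from the SVD of Y'(X W) (V-step); the
penalty is normalized per observation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import MultiTaskElasticNet
from sklearn.model_selection import KFold

from .transcriptomics import (ExpressionBundle, GeneSelectionParams,
                              normalize_expression, select_variable_genes)

__all__ = [
    "RRRModel",
    "preprocess",
    "standardize",
    "fit_rrr",
    "predict",
    "r_squared",
    "cross_validate",
    "biplot_correlations",
]


# --------------------------------------------------------------------------
# Preprocessing
# --------------------------------------------------------------------------

def standardize(M: np.ndarray, warn_constant: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize; zero-variance columns are dropped with a warning.

    Returns (standardized matrix, boolean mask of kept columns).
    """
    M = np.asarray(M, dtype=float)
    sd = M.std(axis=0)
    keep = sd > 0
    if warn_constant and not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance columns")
    return (M[:, keep] - M[:, keep].mean(axis=0)) / sd[keep], keep


def counts_to_cpm_log(counts_per_cell: np.ndarray) -> np.ndarray:
    """Counts (genes x cells) -> CPM -> log2(x + 1), returned genes x cells."""
    totals = counts_per_cell.sum(axis=0, keepdims=True)
    cpm = counts_per_cell / np.where(totals > 0, totals, 1.0) * 1e6
    return np.log2(cpm + 1.0)


def preprocess(
    features: np.ndarray,
    bundle: ExpressionBundle,
    n_genes: int = 1000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(Y, X, gene indices): standardized features and expression.

    Expression is gene-length normalized (exon + intron), converted to CPM,
    log2(x + 1)-transformed and standardized; the ``n_genes`` most variable
    genes (selected on raw exonic counts) are retained.  Electrophysiological
    features are standardized.  Cells must be aligned across the two inputs.
    """
    features = np.asarray(features, dtype=float)
    if features.shape[0] != bundle.n_cells:
        raise ValueError("feature matrix and expression bundle differ in cells")
    params = GeneSelectionParams.for_platform(bundle.platform, n_genes)
    gene_idx = select_variable_genes(bundle.exon_counts, params)
    norm = 2.0 ** normalize_expression(bundle) - 1.0  # back to linear scale
    logcpm = counts_to_cpm_log(norm)[gene_idx]
    X, keep = standardize(logcpm.T)
    Y, _ = standardize(features)
    return Y, X, gene_idx[keep]


# --------------------------------------------------------------------------
# Model
# --------------------------------------------------------------------------

@dataclass
class RRRModel:
    """Fitted sparse RRR: Y ~ X W V' with orthonormal V columns."""

    W: np.ndarray                 # genes x rank
    V: np.ndarray                 # features x rank
    rank: int
    alpha: float                  # elastic-net mixing (1 = pure lasso)
    lam: float                    # penalty strength (per observation)
    converged: bool = True
    n_iter: int = 0
    loss_path: list[float] = field(default_factory=list)

    @property
    def selected_genes(self) -> np.ndarray:
        return np.nonzero(np.abs(self.W).sum(axis=1) > 0)[0]


def _penalty(W: np.ndarray, alpha: float, lam: float) -> float:
    row_norms = np.linalg.norm(W, axis=1)
    return lam * (alpha * row_norms.sum()
                  + 0.5 * (1.0 - alpha) * (row_norms ** 2).sum())


def _loss(X, Y, W, V, alpha, lam) -> float:
    resid = Y - X @ W @ V.T
    return float(np.sum(resid ** 2) / (2.0 * X.shape[0])
                 + _penalty(W, alpha, lam))


def _w_step(X, YV, alpha, lam) -> np.ndarray:
    if lam <= 0:
        W, *_ = np.linalg.lstsq(X, YV, rcond=None)
        return W
    enet = MultiTaskElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=False,
                               max_iter=3000, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        enet.fit(X, YV)
    return enet.coef_.T


def _v_step(X, Y, W) -> np.ndarray:
    M = Y.T @ (X @ W)                     # q x r
    U, _, Vt = np.linalg.svd(M, full_matrices=False)
    return U @ Vt


def fit_rrr(
    X: np.ndarray,
    Y: np.ndarray,
    rank: int = 5,
    alpha: float = 1.0,
    lam: float = 0.5,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int = 0,
    relaxed_refit: bool = False,
) -> RRRModel:
    """Fit sparse RRR by alternating optimization.

    V is initialized from the top-``rank`` right singular vectors of the
    ridge-regression prediction of Y (seed-controlled jitter breaks
    degenerate spectra); iterations stop when the relative loss change falls
    below ``tol`` or after ``max_iter`` rounds (non-convergence returns the
    best iterate, flagged).  ``relaxed_refit`` re-estimates W and V without
    penalty on the selected gene support (off by default: the convention of
    whether weights are reported shrunken or relaxed is genuinely open).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    n, p = X.shape
    q = Y.shape[1]
    rank = min(rank, q)

    ridge = np.linalg.solve(X.T @ X + 1e-3 * np.eye(p), X.T @ Y)
    Yhat = X @ ridge
    _, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    if s.size > rank and abs(s[rank - 1] - s[rank]) < 1e-12 * max(s[0], 1.0):
        rng = np.random.default_rng(seed)
        Vt = Vt + rng.normal(scale=1e-8, size=Vt.shape)
    V = Vt[:rank].T

    best = None
    prev = np.inf
    converged = False
    it = 0
    losses = []
    W = np.zeros((p, rank))
    for it in range(1, max_iter + 1):
        W = _w_step(X, Y @ V, alpha, lam)
        V = _v_step(X, Y, W)
        cur = _loss(X, Y, W, V, alpha, lam)
        losses.append(cur)
        if best is None or cur <= best[0]:
            best = (cur, W.copy(), V.copy())
        if np.isfinite(prev) and abs(prev - cur) <= tol * max(abs(prev), 1e-12):
            converged = True
            break
        prev = cur
    if not converged:
        warnings.warn("sparse RRR did not converge; returning best iterate")
    _, W, V = best
    if relaxed_refit:
        support = np.nonzero(np.abs(W).sum(axis=1) > 0)[0]
        if 0 < support.size < p:
            Xs = X[:, support]
            for _ in range(20):
                Ws, *_ = np.linalg.lstsq(Xs, Y @ V, rcond=None)
                V = _v_step(Xs, Y, Ws)
            W = np.zeros((p, rank))
            W[support] = Ws
    return RRRModel(W=W, V=V, rank=rank, alpha=alpha, lam=lam,
                    converged=converged, n_iter=it, loss_path=losses)


def predict(model: RRRModel, X: np.ndarray) -> np.ndarray:
    return X @ model.W @ model.V.T


def r_squared(model: RRRModel, X: np.ndarray, Y: np.ndarray) -> float:
    """Test R^2 = 1 - ||Y - X W V'||^2 / ||Y||^2 (Y already standardized)."""
    resid = Y - predict(model, X)
    return float(1.0 - np.sum(resid ** 2) / np.sum(Y ** 2))


# --------------------------------------------------------------------------
# Cross-validation and biplots
# --------------------------------------------------------------------------

def cross_validate(
    X: np.ndarray,
    Y: np.ndarray,
    ranks=(5,),
    alphas=(0.5, 0.75, 1.0),
    lams=(0.2, 0.5, 1.0, 2.0, 4.0, 6.0),
    folds: int = 10,
    seed: int = 0,
    max_iter: int = 50,
) -> pd.DataFrame:
    """Grid cross-validation: per (rank, alpha, lambda), the mean test R^2,
    mean selected-gene count and mean per-component test correlations
    corr(X W_k, Y V_k)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    for tr, te in splits:
        if len(te) < 2:
            raise ValueError("fold with fewer than 2 cells")
    rows = []
    for r in ranks:
        for a in alphas:
            for lam in lams:
                r2s, ngenes, comps = [], [], []
                for tr, te in splits:
                    m = fit_rrr(X[tr], Y[tr], rank=r, alpha=a, lam=lam,
                                max_iter=max_iter)
                    r2s.append(r_squared(m, X[te], Y[te]))
                    ngenes.append(len(m.selected_genes))
                    Z = X[te] @ m.W
                    T = Y[te] @ m.V
                    cc = []
                    for k in range(m.rank):
                        if Z[:, k].std() > 0 and T[:, k].std() > 0:
                            cc.append(float(np.corrcoef(Z[:, k], T[:, k])[0, 1]))
                        else:
                            cc.append(float("nan"))
                    comps.append(cc)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    comp_mean = np.nanmean(np.array(comps), axis=0).tolist()
                rows.append(dict(
                    rank=r, alpha=a, lam=lam,
                    mean_r2=float(np.mean(r2s)),
                    mean_n_genes=float(np.mean(ngenes)),
                    component_corrs=comp_mean,
                ))
    return pd.DataFrame(rows)


def biplot_correlations(
    model: RRRModel,
    X: np.ndarray,
    Y: np.ndarray,
    dims: tuple[int, int] = (0, 1),
    threshold: float = 0.4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlations of every gene (X column) and feature (Y column) with the
    latent scores X W, plus a display mask.

    The mask keeps variables whose correlation-line length over the two
    displayed latent dimensions exceeds ``threshold`` (the biplot circle has
    radius 1); constant columns get NaN correlations and are masked out.
    """
    Z = X @ model.W
    out = []
    for name, M in (("gene", X), ("feature", Y)):
        sd_m = M.std(axis=0)
        sd_z = Z.std(axis=0)
        Mc = M - M.mean(axis=0)
        Zc = Z - Z.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (Mc.T @ Zc) / M.shape[0] / np.outer(sd_m, sd_z)
        corr[sd_m == 0, :] = np.nan
        length = np.sqrt(np.nansum(corr[:, list(dims)] ** 2, axis=1))
        length[np.isnan(corr[:, dims[0]])] = np.nan
        df = pd.DataFrame(corr, columns=[f"latent_{k}" for k in range(Z.shape[1])])
        df["line_length"] = length
        df["display"] = length > threshold
        df.loc[np.isnan(length), "display"] = False
        out.append(df)
    return out[0], out[1]
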