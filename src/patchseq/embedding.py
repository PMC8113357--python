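"""Phenotype representations, t-SNE embedding and kNN family classification.

The representations mirror the preprocessing used for the published
phenotype maps: standardized features are reduced by PCA and every PC set is
rescaled by the standard deviation of its own PC1 (or PC2 for the z-profile
block, whose PC1 tracks soma depth and is discarded), so that heterogeneous
blocks contribute comparable variance.  The t-SNE optimizer itself is an
external algorithm consumed with a pinned parameter contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "Representation",
    "ReferenceEmbedding",
    "build_ephys_representation",
    "build_morph_representation",
    "build_combined_representation",
    "embed_tsne",
    "position_on_reference",
    "knn_family_classify",
    "coverage_ellipse",
]


@dataclass
class Representation:
    """cells x dims matrix plus block structure and scaling provenance."""

    matrix: np.ndarray
    blocks: dict[str, slice]
    provenance: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ReferenceEmbedding:
    """Reference 2D positions plus the high-dimensional log expression (and
    gene set) used to find neighbours for new cells."""

    positions: np.ndarray       # cells x 2
    log_expression: np.ndarray  # cells x genes
    genes: np.ndarray | None = None


def _fixed_sign_pca(X: np.ndarray, n_components: int, seed: int = 0) -> tuple[np.ndarray, PCA]:
    """PCA with a deterministic sign convention: the loading of largest
    magnitude on each component is made positive."""
    pca = PCA(n_components=n_components, random_state=seed)
    scores = pca.fit_transform(X)
    for k in range(pca.components_.shape[0]):
        j = int(np.argmax(np.abs(pca.components_[k])))
        if pca.components_[k, j] < 0:
            pca.components_[k] *= -1
            scores[:, k] *= -1
    return scores, pca


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def build_ephys_representation(
    feature_vectors: np.ndarray, n_pcs: int = 17
) -> Representation:
    """Electrophysiological representation: standardize, PCA, then divide
    every PC by the standard deviation of PC1 (so sd(PC1) = 1)."""
    X = np.asarray(feature_vectors, dtype=float)
    if X.shape[0] < X.shape[1]:
        raise ValueError("need at least as many cells as features")
    n_pcs = min(n_pcs, X.shape[1])
    scores, _ = _fixed_sign_pca(_standardize(X), n_pcs)
    scale = scores[:, 0].std()
    scores = scores / scale
    return Representation(
        matrix=scores, blocks={"ephys": slice(0, n_pcs)},
        provenance={"n_pcs": n_pcs, "pc1_sd": float(scale)})


def _class_block(
    morpho: np.ndarray, zprof: np.ndarray, n_morpho_pcs: int, n_z_pcs: int
) -> np.ndarray:
    """Per-class 24-dim block: 20 morphometric PCs scaled by sd(PC1) plus
    z-profile PCs 2..5 scaled by sd(PC2)."""
    m_scores, _ = _fixed_sign_pca(_standardize(morpho),
                                  min(n_morpho_pcs, morpho.shape[1]))
    m_scores = m_scores / m_scores[:, 0].std()
    z_scores, _ = _fixed_sign_pca(_standardize(zprof),
                                  min(n_z_pcs, zprof.shape[1]))
    z_scores = z_scores[:, 1:] / z_scores[:, 1].std()  # discard PC1
    return np.hstack([m_scores, z_scores])


def build_morph_representation(
    morphometrics_by_class: dict[str, np.ndarray],
    z_profiles_by_class: dict[str, np.ndarray],
    cell_class: np.ndarray,
    n_morpho_pcs: int = 20,
    n_z_pcs: int = 5,
    excitatory_offset: float = 0.25,
) -> Representation:
    """Block-diagonal morphological representation.

    Each class (excitatory: dendritic z-profiles; inhibitory: axonal) gets
    its own 24-dim block (20 morphometric PCs + z-profile PCs 2-5, each set
    scaled as described); the two blocks are assembled block-diagonally and
    a small constant offset is added to the excitatory block to keep the two
    populations apart in the embedding.
    """
    classes = ["excitatory", "inhibitory"]
    cell_class = np.asarray(cell_class)
    block_data = {}
    width = {}
    for cls in classes:
        if cls not in morphometrics_by_class:
            continue
        block = _class_block(np.asarray(morphometrics_by_class[cls], dtype=float),
                             np.asarray(z_profiles_by_class[cls], dtype=float),
                             n_morpho_pcs, n_z_pcs)
        block_data[cls] = block
        width[cls] = block.shape[1]
    total = sum(width.values())
    out = np.zeros((cell_class.size, total))
    blocks = {}
    col = 0
    counters = {cls: 0 for cls in block_data}
    for cls in classes:
        if cls not in block_data:
            continue
        blocks[cls] = slice(col, col + width[cls])
        col += width[cls]
    for i, cls in enumerate(cell_class):
        row = block_data[cls][counters[cls]]
        counters[cls] += 1
        out[i, blocks[cls]] = row
        if cls == "excitatory":
            out[i, blocks[cls]] += excitatory_offset
    return Representation(matrix=out, blocks=blocks,
                          provenance={"excitatory_offset": excitatory_offset})


def build_combined_representation(
    morph_rep: Representation,
    ephys_rep: Representation,
    ephys_scale: float = np.sqrt(2.0),
) -> Representation:
    """Stack morphological and electrophysiological blocks (cells aligned),
    multiplying the ephys block by sqrt(2) so its total variance is on the
    scale of the two-part morphological block."""
    if morph_rep.n_cells != ephys_rep.n_cells:
        raise ValueError("representations must cover the same cells")
    if morph_rep.n_cells == 0:
        raise ValueError("empty cell intersection")
    m = morph_rep.matrix
    e = ephys_rep.matrix * ephys_scale
    blocks = dict(morph_rep.blocks)
    blocks["ephys"] = slice(m.shape[1], m.shape[1] + e.shape[1])
    return Representation(
        matrix=np.hstack([m, e]), blocks=blocks,
        provenance={"ephys_scale": float(ephys_scale)})


def transcriptomic_tsne_input(
    umi_counts: np.ndarray, n_pcs: int = 50, seed: int = 0
) -> np.ndarray:
    """Preprocess reference UMI counts (genes x cells) for a t-SNE run.

    Counts are normalized by each cell's sequencing depth, multiplied by the
    median depth, log2(x + 1)-transformed, and reduced to ``n_pcs``
    principal components (cells x PCs).
    """
    counts = np.asarray(umi_counts, dtype=float)
    depth = counts.sum(axis=0)
    depth = np.where(depth > 0, depth, 1.0)
    norm = counts / depth * np.median(depth)
    log = np.log2(norm + 1.0).T
    scores, _ = _fixed_sign_pca(log - log.mean(axis=0),
                                min(n_pcs, min(log.shape) - 1), seed)
    return scores


def embed_tsne(
    matrix: np.ndarray,
    perplexity: float = 30.0,
    early_exaggeration: float = 4.0,
    seed: int = 0,
    init: np.ndarray | str = "pca-scaled",
) -> tuple[np.ndarray, dict]:
    """2D t-SNE with the pinned parameter contract: learning rate n/12,
    early exaggeration 4 and scaled-PCA initialization (PCA coordinates
    rescaled to sd 1e-4).  Returns (positions, provenance)."""
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if n < 3 * perplexity:
        warnings.warn("fewer than 3 x perplexity points; embedding may distort")
        perplexity = max(min(perplexity, (n - 1) / 3.0), 2.0)
    if isinstance(init, str) and init == "pca-scaled":
        scores, _ = _fixed_sign_pca(X - X.mean(axis=0), 2, seed)
        init_arr = scores / scores[:, 0].std() * 1e-4
        init_name = "scaled-pca"
    else:
        init_arr = np.asarray(init, dtype=float)
        init_name = "user"
    lr = max(n / 12.0, 10.0)
    ts = TSNE(n_components=2, perplexity=perplexity,
              early_exaggeration=early_exaggeration, learning_rate=lr,
              init=init_arr, random_state=seed)
    pos = ts.fit_transform(X)
    prov = {"perplexity": float(perplexity), "early_exaggeration": early_exaggeration,
            "learning_rate": lr, "init": init_name, "seed": seed}
    return pos, prov


def position_on_reference(
    query_log_expr: np.ndarray,
    reference: ReferenceEmbedding,
    k: int = 10,
) -> np.ndarray:
    """Place query cells on a reference embedding without re-optimizing.

    Each query cell lands at the coordinate-wise median of the 2D positions
    of its k nearest reference cells under Pearson correlation distance in
    the high-dimensional expression space.
    """
    R = np.asarray(reference.log_expression, dtype=float)
    if k > R.shape[0]:
        raise ValueError("k exceeds the reference size")
    Q = np.atleast_2d(np.asarray(query_log_expr, dtype=float))
    Rc = R - R.mean(axis=1, keepdims=True)
    Qc = Q - Q.mean(axis=1, keepdims=True)
    Rn = Rc / np.linalg.norm(Rc, axis=1, keepdims=True)
    Qn = Qc / np.linalg.norm(Qc, axis=1, keepdims=True)
    corr = Qn @ Rn.T
    out = np.empty((Q.shape[0], 2))
    for i in range(Q.shape[0]):
        nn = np.argsort(-corr[i])[:k]
        out[i] = np.median(reference.positions[nn], axis=0)
    return out if query_log_expr.ndim > 1 else out[0]


def knn_family_classify(
    representation: np.ndarray,
    families: np.ndarray,
    k: int = 10,
) -> tuple[np.ndarray, "np.ndarray", list[str]]:
    """Leave-one-out kNN classification of transcriptomic families.

    Each cell is classified by the majority family among its k nearest
    neighbours (Euclidean metric, the cell itself excluded); majority ties
    go to the single nearest neighbour's family.  Returns (predictions,
    row-normalized confusion matrix in percent, family order).
    """
    X = np.asarray(representation, dtype=float)
    families = np.asarray(families)
    fams = sorted(set(families))
    for f in fams:
        if np.count_nonzero(families == f) < k + 1:
            warnings.warn(f"family {f} has fewer than k+1 cells")
    nn = NearestNeighbors(n_neighbors=min(k + 1, X.shape[0])).fit(X)
    _, idx = nn.kneighbors(X)
    preds = np.empty(X.shape[0], dtype=families.dtype)
    for i in range(X.shape[0]):
        neigh = [j for j in idx[i] if j != i][:k]
        labels, counts = np.unique(families[neigh], return_counts=True)
        top = counts.max()
        winners = set(labels[counts == top])
        if len(winners) == 1:
            preds[i] = next(iter(winners))
        else:
            preds[i] = next(families[j] for j in neigh if families[j] in winners)
    conf = np.zeros((len(fams), len(fams)))
    for i, fa in enumerate(fams):
        m = families == fa
        for j, fb in enumerate(fams):
            conf[i, j] = np.count_nonzero(preds[m] == fb)
        if conf[i].sum() > 0:
            conf[i] = conf[i] / conf[i].sum() * 100.0
    return preds, conf, fams


def coverage_ellipse(
    points: np.ndarray, coverage: float = 0.8
) -> tuple[np.ndarray, np.ndarray, float]:
    """(center, covariance, scale) of the Gaussian coverage ellipse: the
    contour of the fitted normal containing ``coverage`` probability mass
    (chi-square quantile with 2 degrees of freedom)."""
    P = np.asarray(points, dtype=float)
    center = P.mean(axis=0)
    cov = np.cov(P.T)
    return center, cov, float(chi2.ppf(coverage, df=2))


def point_in_coverage_ellipse(
    point: np.ndarray, center: np.ndarray, cov: np.ndarray, scale: float
) -> bool:
    d = np.asarray(point) - center
    return float(d @ np.linalg.solve(cov, d)) <= scale
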