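"""Within-t-type variability and between-t-type distance structure.

The central statistic is the normalized total variance of a t-type: the sum
over feature dimensions of the within-type (population) variance divided by
the same sum over the whole data set.  It is 0 when all cells of the type
are identical and 1 when the type is as variable as the full data set.
A k-means clustering into as many clusters as there are qualifying t-types
provides a baseline band for morpho-electrically homogeneous groups, and the
entropy of Leiden cluster memberships per t-type offers a partition-based
alternative.  The within-family analysis relates pairwise t-type distances
across modalities.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "normalized_total_variance",
    "kmeans_baseline",
    "leiden_entropy",
    "pairwise_type_distances",
    "distance_correlation",
    "restrict_to_majority_layer",
]


def restrict_to_majority_layer(
    type_labels: np.ndarray, layer_labels: np.ndarray
) -> np.ndarray:
    """Mask keeping, for each t-type, only the cells from its majority layer
    (ties broken by the alphabetically first layer, deterministically).

    Used for layer-restricted morphological analyses, where a type spread
    over layers would otherwise look artificially variable.
    """
    type_labels = np.asarray(type_labels)
    layer_labels = np.asarray(layer_labels)
    mask = np.zeros(type_labels.size, dtype=bool)
    for t in np.unique(type_labels):
        m = type_labels == t
        layers, counts = np.unique(layer_labels[m], return_counts=True)
        majority = layers[np.argmax(counts)]
        mask |= m & (layer_labels == majority)
    return mask


def normalized_total_variance(
    features: np.ndarray, member_mask: np.ndarray
) -> float:
    """Within-type total variance normalized by the whole-data-set total.

    Both numerator and denominator use population normalization (1/|T| and
    1/n); undefined for types with fewer than two members.
    """
    X = np.asarray(features, dtype=float)
    m = np.asarray(member_mask, dtype=bool)
    if m.sum() < 2:
        return float("nan")
    within = np.sum(np.var(X[m], axis=0))     # ddof=0: population variance
    total = np.sum(np.var(X, axis=0))
    if total == 0:
        return float("nan")
    return float(within / total)


def kmeans_baseline(
    features: np.ndarray, K: int, seed: int = 0
) -> tuple[float, float]:
    """(min, max) normalized total variance across K k-means clusters.

    K should equal the number of qualifying t-types; the clusters bound how
    homogeneous groups can be given the data's own variability.
    """
    X = np.asarray(features, dtype=float)
    if K > X.shape[0]:
        raise ValueError("K exceeds the number of cells")
    if K == 1:
        return 1.0, 1.0
    km = KMeans(n_clusters=K, random_state=seed, n_init=10).fit(X)
    variances = [
        normalized_total_variance(X, km.labels_ == c)
        for c in range(K)
        if np.count_nonzero(km.labels_ == c) >= 2
    ]
    return float(np.min(variances)), float(np.max(variances))


def _knn_graph(X: np.ndarray, k: int) -> ig.Graph:
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    edges = {tuple(sorted((i, int(j)))) for i in range(X.shape[0])
             for j in idx[i] if int(j) != i}
    return ig.Graph(n=X.shape[0], edges=list(edges))


def _leiden(graph: ig.Graph, resolution: float, seed: int) -> np.ndarray:
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed)
    return np.asarray(part.membership)


def tune_leiden_resolution(
    graph: ig.Graph, target_clusters: int, seed: int = 0,
    lo: float = 1e-3, hi: float = 20.0, n_iter: int = 30,
) -> float:
    """Binary search on the resolution parameter to hit a target cluster
    count (within +/- 1)."""
    for _ in range(n_iter):
        mid = np.sqrt(lo * hi)
        n = len(np.unique(_leiden(graph, mid, seed)))
        if abs(n - target_clusters) <= 1:
            return float(mid)
        if n > target_clusters:
            hi = mid
        else:
            lo = mid
    return float(np.sqrt(lo * hi))


def shannon_entropy_bits(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def leiden_entropy(
    features: np.ndarray,
    type_labels: np.ndarray,
    target_clusters: int = 5,
    resolution: float | None = None,
    k: int = 10,
    n_rep: int = 100,
    subsample: int = 10,
    min_cells: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Entropy of Leiden cluster memberships per t-type.

    The kNN graph (k = 10) is Leiden-clustered (resolution tuned to a target
    cluster count unless given); each qualifying t-type (>= ``min_cells``
    cells) is subsampled to ``subsample`` cells and the Shannon entropy of
    its cluster-ID distribution recorded.  Clustering and subsampling are
    repeated ``n_rep`` times with fresh seeds; returns a tidy frame of
    (t-type, repetition, entropy_bits, n_clusters).
    """
    X = np.asarray(features, dtype=float)
    type_labels = np.asarray(type_labels)
    graph = _knn_graph(X, k)
    if resolution is None:
        resolution = tune_leiden_resolution(graph, target_clusters, seed)
    qualifying = [t for t in np.unique(type_labels)
                  if np.count_nonzero(type_labels == t) >= min_cells]
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(n_rep)
    rows = []
    for r in range(n_rep):
        membership = _leiden(graph, resolution, int(rep_seeds[r] % (2 ** 31)))
        rng = np.random.default_rng(rep_seeds[r])
        for t in qualifying:
            idx = np.nonzero(type_labels == t)[0]
            sub = rng.choice(idx, size=subsample, replace=False)
            rows.append(dict(
                ttype=t, repetition=r,
                entropy_bits=shannon_entropy_bits(membership[sub]),
                n_clusters=int(len(np.unique(membership)))))
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Within-family distance analysis
# --------------------------------------------------------------------------

@dataclass
class DistancePairTable:
    """Per within-family t-type pair: distances in each modality."""

    table: pd.DataFrame


def pairwise_type_distances(
    centroid_log_expr: dict[str, np.ndarray],
    feature_vectors: np.ndarray,
    type_labels: np.ndarray,
    family_of_type: dict[str, str],
    soma_depths: np.ndarray | None = None,
    min_cells: int = 5,
) -> DistancePairTable:
    """Pairwise distances between t-types of the same family.

    Transcriptomic distance is 1 - Pearson correlation between reference
    centroid log expressions; electrophysiological distance is the Euclidean
    distance between mean feature vectors; soma-depth distance is the
    absolute difference of mean normalized depths.  Only t-types with at
    least ``min_cells`` assigned cells enter.
    """
    type_labels = np.asarray(type_labels)
    X = np.asarray(feature_vectors, dtype=float)
    qualifying = [t for t in centroid_log_expr
                  if np.count_nonzero(type_labels == t) >= min_cells]
    means = {t: X[type_labels == t].mean(axis=0) for t in qualifying}
    depths = None
    if soma_depths is not None:
        soma_depths = np.asarray(soma_depths, dtype=float)
        depths = {t: float(np.nanmean(soma_depths[type_labels == t]))
                  for t in qualifying}
    rows = []
    for t1, t2 in itertools.combinations(qualifying, 2):
        if family_of_type[t1] != family_of_type[t2]:
            continue
        r = pearsonr(centroid_log_expr[t1], centroid_log_expr[t2]).statistic
        row = dict(
            type_a=t1, type_b=t2, family=family_of_type[t1],
            transcriptomic_distance=float(1.0 - r),
            ephys_distance=float(np.linalg.norm(means[t1] - means[t2])),
        )
        if depths is not None:
            row["soma_depth_distance"] = abs(depths[t1] - depths[t2])
        rows.append(row)
    return DistancePairTable(table=pd.DataFrame(rows))


def distance_correlation(
    pairs: DistancePairTable,
    x: str = "transcriptomic_distance",
    y: str = "ephys_distance",
    per_family: bool = False,
) -> float | pd.Series:
    """Pearson correlation between two distance columns, pooled across
    families (or per family with ``per_family=True``)."""
    df = pairs.table
    if len(df) < 3:
        raise ValueError("need at least 3 pairs")
    if per_family:
        return df.groupby("family").apply(
            lambda g: pearsonr(g[x], g[y]).statistic if len(g) >= 3 else np.nan)
    if df[x].std() == 0 or df[y].std() == 0:
        return float("nan")
    return float(pearsonr(df[x], df[y]).statistic)
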