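"""Clustering and embedding of tissue space and gene space.

Hierarchical clustering uses 1 - Pearson correlation (continuous
profiles) or Jaccard distance (binary differential-expression patterns)
with Ward linkage.  k-means under correlation distance runs on
row-standardized vectors (z-scored rows, whose Euclidean distance is
monotone in 1 - r) with multiple restarts, selecting k by mean
silhouette under the same correlation distance.  PCA operates on the
log-shifted matrix with genes as observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score


@dataclass
class ClusteringResult:
    assignment: pd.Series  # item -> cluster id
    k: int
    method: str  # "hierarchical" | "kmeans"
    distance: str  # "one-minus-pearson" | "jaccard"
    linkage_matrix: np.ndarray | None = None
    silhouette_by_k: pd.DataFrame | None = None
    centroids: pd.DataFrame | None = None
    excluded: list[str] = field(default_factory=list)


def _drop_constant_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    sd = matrix.to_numpy(dtype=float).std(axis=1)
    excluded = [i for i, s in zip(matrix.index, sd) if s == 0]
    if excluded:
        warnings.warn(
            f"{len(excluded)} constant rows excluded from correlation-distance clustering",
            stacklevel=3,
        )
    return matrix.loc[sd > 0], excluded


def hierarchical_cluster(
    matrix: pd.DataFrame, distance: str = "one-minus-pearson", k: int | None = None
) -> ClusteringResult:
    """Ward-linkage agglomerative clustering of the matrix rows.

    ``distance`` is "one-minus-pearson" for continuous profiles or
    "jaccard" for binary patterns.  With ``k`` given, flat clusters are
    cut from the dendrogram (maxclust); otherwise only the dendrogram is
    returned (assignment all ones).
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least two items to cluster")
    excluded: list[str] = []
    if distance == "one-minus-pearson":
        matrix, excluded = _drop_constant_rows(matrix)
        d = pdist(matrix.to_numpy(dtype=float), metric="correlation")
    elif distance == "jaccard":
        values = matrix.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("jaccard distance requires a binary matrix")
        d = pdist(values.astype(bool), metric="jaccard")
    else:
        raise ValueError(f"unknown distance: {distance}")
    link = hierarchy.linkage(d, method="ward")
    if k is not None:
        labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    else:
        labels = np.ones(matrix.shape[0], dtype=int)
    assignment = pd.Series(labels, index=matrix.index, name="cluster")
    return ClusteringResult(
        assignment=assignment,
        k=int(assignment.nunique()),
        method="hierarchical",
        distance=distance,
        linkage_matrix=link,
        excluded=excluded,
    )


def double_hierarchical(
    matrix: pd.DataFrame, distance: str = "one-minus-pearson"
) -> tuple[ClusteringResult, ClusteringResult]:
    """Cluster both axes (rows = genes, columns = entities)."""
    return hierarchical_cluster(matrix, distance), hierarchical_cluster(matrix.T, distance)


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(link)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = walk(node.get_left()), walk(node.get_right())
        dl = node.dist - node.get_left().dist
        dr = node.dist - node.get_right().dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return walk(tree) + ";"


def _standardize_rows(matrix: pd.DataFrame) -> np.ndarray:
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    return (values - mean) / np.where(sd > 0, sd, 1.0)


def kmeans_select_k(
    matrix: pd.DataFrame,
    k_grid: list[int] | None = None,
    repeats: int = 10,
    seed: int = 0,
    silhouette_subsample: int = 2000,
) -> ClusteringResult:
    """k-means over a k grid with silhouette-based selection of k.

    Rows are z-scored so Euclidean k-means realizes correlation distance;
    each k runs ``repeats`` restarts keeping the best within-cluster
    objective; k* maximizes the mean silhouette under correlation
    distance (ties broken toward the smallest k).  For large gene sets
    the silhouette is computed on a fixed-seed subsample.
    """
    matrix, excluded = _drop_constant_rows(matrix)
    n = matrix.shape[0]
    if k_grid is None:
        k_grid = list(range(2, min(101, n)))
    k_grid = [k for k in k_grid if 2 <= k <= n - 1]
    if not k_grid:
        raise ValueError("empty or out-of-range k grid")
    z = _standardize_rows(matrix)
    rng = np.random.default_rng(seed)
    sil_idx = np.arange(n)
    if n > 5000:
        sil_idx = rng.choice(n, size=silhouette_subsample, replace=False)
    rows = []
    best = None
    for k in k_grid:
        km = KMeans(n_clusters=k, n_init=repeats, random_state=int(rng.integers(2**31 - 1)))
        labels = km.fit_predict(z)
        if len(set(labels[sil_idx])) < 2:
            sil = np.nan
        else:
            sil = float(silhouette_score(matrix.to_numpy()[sil_idx], labels[sil_idx], metric="correlation"))
        rows.append({"k": k, "silhouette": sil, "inertia": float(km.inertia_)})
        if not np.isnan(sil) and (best is None or sil > best[0] + 1e-12):
            best = (sil, k, labels, km)
    if best is None:
        raise ValueError("silhouette undefined for every k (identical items?)")
    _, k_star, labels, km = best
    assignment = pd.Series(labels + 1, index=matrix.index, name="cluster")
    centroids = pd.DataFrame(
        [matrix.to_numpy()[labels == c].mean(axis=0) for c in range(k_star)],
        index=[c + 1 for c in range(k_star)],
        columns=matrix.columns,
    )
    return ClusteringResult(
        assignment=assignment,
        k=k_star,
        method="kmeans",
        distance="one-minus-pearson",
        silhouette_by_k=pd.DataFrame(rows),
        centroids=centroids,
        excluded=excluded,
    )


def pca_project(
    matrix: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Centered PCA of the (log-shifted) matrix, genes as observations.

    Returns (scores with PC columns, explained-variance fractions
    (non-increasing), component loadings).  With all components retained,
    ``scores @ components + column means`` reconstructs the matrix.
    """
    if n_components > min(matrix.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(matrix dims)={min(matrix.shape)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix.to_numpy(dtype=float))
    cols = [f"PC{i + 1}" for i in range(n_components)]
    components = pd.DataFrame(pca.components_, index=cols, columns=matrix.columns)
    return (
        pd.DataFrame(scores, index=matrix.index, columns=cols),
        pca.explained_variance_ratio_,
        components,
    )
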