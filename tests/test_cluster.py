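"""Hierarchical/Ward clustering, silhouette-selected k-means, PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from protatlas import cluster

from .conftest import brute_silhouette, naive_ward_linkage


def _modular_matrix(n_modules=3, per_module=8, n_entities=30, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for m in range(n_modules):
        profile = rng.normal(0, 1, n_entities)
        for _ in range(per_module):
            rows.append(profile + rng.normal(0, noise, n_entities))
    idx = [f"m{m}_g{i}" for m in range(n_modules) for i in range(per_module)]
    return pd.DataFrame(rows, index=idx, columns=[f"e{j}" for j in range(n_entities)])


def test_identical_items_merge_at_zero_distance():
    m = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 1.0, 4.0]], index=list("abc"))
    res = cluster.hierarchical_cluster(m, distance="one-minus-pearson", k=2)
    assert res.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)
    assert res.assignment["a"] == res.assignment["b"] != res.assignment["c"]


def test_jaccard_distance_on_binary_patterns():
    m = pd.DataFrame([[1, 1, 0], [0, 1, 1]], index=["p1", "p2"])
    d = pdist(m.to_numpy().astype(bool), metric="jaccard")
    assert d[0] == pytest.approx(2 / 3)  # |sym-diff| / |union|
    res = cluster.hierarchical_cluster(m, distance="jaccard", k=2)
    assert res.k == 2
    with pytest.raises(ValueError):
        cluster.hierarchical_cluster(pd.DataFrame([[1, 2], [0, 1]]), distance="jaccard")


def test_hierarchical_recovers_planted_tissue_groups():
    m = _modular_matrix(n_modules=3, per_module=6)
    res = cluster.hierarchical_cluster(m, distance="one-minus-pearson", k=3)
    groups = {}
    for item, c in res.assignment.items():
        groups.setdefault(item.split("_")[0], set()).add(c)
    assert all(len(v) == 1 for v in groups.values())
    assert len({next(iter(v)) for v in groups.values()}) == 3


def test_ward_matches_naive_lance_williams_oracle():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, (11, 6))
    d = pdist(x, metric="euclidean")
    ours = hierarchy.linkage(d, method="ward")
    oracle = naive_ward_linkage(squareform(d))
    assert np.allclose(np.sort(ours[:, 2]), np.sort(oracle[:, 2]), atol=1e-9)
    for k in (2, 3, 4):
        a = hierarchy.fcluster(ours, k, criterion="maxclust")
        b = hierarchy.fcluster(
            np.column_stack([oracle[:, :2], oracle[:, 2], oracle[:, 3]]), k, criterion="maxclust"
        )
        # same partition up to label renaming
        assert len(set(zip(a, b))) == k


def test_double_clustering_covers_both_axes():
    m = _modular_matrix()
    genes_res, entity_res = cluster.double_hierarchical(m)
    assert set(genes_res.assignment.index) == set(m.index)
    assert set(entity_res.assignment.index) == set(m.columns)


def test_newick_export_is_parseable():
    m = _modular_matrix(n_modules=2, per_module=3)
    res = cluster.hierarchical_cluster(m, k=2)
    nwk = cluster.linkage_to_newick(res.linkage_matrix, list(res.assignment.index))
    assert nwk.endswith(";") and nwk.count("(") == len(m) - 1
    from io import StringIO

    from Bio import Phylo

    tree = Phylo.read(StringIO(nwk), "newick")
    assert {t.name for t in tree.get_terminals()} == set(m.index)


def test_kmeans_selects_planted_k_and_is_deterministic():
    m = _modular_matrix(n_modules=4, per_module=8, noise=0.02, seed=1)
    res = cluster.kmeans_select_k(m, k_grid=list(range(2, 9)), seed=7)
    assert res.k == 4
    for mod in ("m0", "m1", "m2", "m3"):
        labels = {res.assignment[g] for g in res.assignment.index if g.startswith(mod)}
        assert len(labels) == 1
    res2 = cluster.kmeans_select_k(m, k_grid=list(range(2, 9)), seed=7)
    pd.testing.assert_series_equal(res.assignment, res2.assignment)
    assert res.centroids.shape == (4, m.shape[1])


def test_kmeans_best_of_restarts_objective():
    m = _modular_matrix(n_modules=3, per_module=10, noise=0.4, seed=2)
    from sklearn.cluster import KMeans

    z = (m.to_numpy() - m.to_numpy().mean(axis=1, keepdims=True)) / m.to_numpy().std(
        axis=1, keepdims=True
    )
    multi = KMeans(n_clusters=3, n_init=10, random_state=0).fit(z)
    singles = [KMeans(n_clusters=3, n_init=1, random_state=s).fit(z).inertia_ for s in range(5)]
    assert all(multi.inertia_ <= s + 1e-9 for s in singles)


def test_silhouette_matches_brute_force():
    m = _modular_matrix(n_modules=3, per_module=10, noise=0.3, seed=4)
    res = cluster.kmeans_select_k(m, k_grid=[3], seed=0)
    from sklearn.metrics import silhouette_score

    labels = res.assignment.to_numpy()
    ours = silhouette_score(m.to_numpy(), labels, metric="correlation")
    d = squareform(pdist(m.to_numpy(), metric="correlation"))
    assert ours == pytest.approx(brute_silhouette(d, labels), abs=1e-9)


def test_kmeans_identical_items_silhouette_undefined():
    import warnings

    m = pd.DataFrame(np.tile([1.0, 2.0, 3.0], (6, 1)), index=[f"g{i}" for i in range(6)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # k-means collapses duplicate points
        with pytest.raises(ValueError, match="silhouette undefined"):
            cluster.kmeans_select_k(m, k_grid=[2], seed=0)


def test_pca_rank_one_and_reconstruction():
    rng = np.random.default_rng(5)
    u = rng.normal(0, 1, 15)
    v = rng.normal(0, 1, 8)
    m = pd.DataFrame(np.outer(u, v), index=[f"g{i}" for i in range(15)])
    scores, evr, _ = cluster.pca_project(m, n_components=2)
    assert evr[0] == pytest.approx(1.0, abs=1e-9)
    full = pd.DataFrame(rng.normal(0, 1, (10, 6)))
    s, evr2, comps = cluster.pca_project(full, n_components=6)
    recon = s.to_numpy() @ comps.to_numpy() + full.to_numpy().mean(axis=0)
    assert np.allclose(recon, full.to_numpy(), atol=1e-9)
    assert (np.diff(evr2) <= 1e-12).all()
    with pytest.raises(ValueError):
        cluster.pca_project(full, n_components=11)


def test_pca_first_component_tracks_breadth():
    """Genes stratified by expression breadth separate along PC1."""
    rng = np.random.default_rng(6)
    n_e = 40
    rows, breadth = [], []
    for _ in range(120):
        k = int(rng.integers(2, n_e + 1))
        vec = np.zeros(n_e)
        on = rng.choice(n_e, size=k, replace=False)
        vec[on] = rng.normal(4, 0.5, k)
        rows.append(vec)
        breadth.append(k)
    m = pd.DataFrame(rows)
    scores, _, _ = cluster.pca_project(m, n_components=2)
    r = np.corrcoef(scores["PC1"], breadth)[0, 1]
    assert abs(r) > 0.5
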