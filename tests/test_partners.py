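"""Pairwise correlation engine, permutation null, partner graph, enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from protatlas import ingest, integrate, partners, profiles
from protatlas.config import SyntheticConfig
from protatlas.synthetic import generate_proteome_sources

from .conftest import naive_pearson


def _random_matrix(n_genes, n_entities=69, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(3, 1, (n_genes, n_entities)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"e{i}" for i in range(n_entities)],
    )


def test_identical_and_opposite_vectors():
    base = np.arange(10.0)
    m = pd.DataFrame([base, base, -base], index=["a", "b", "c"], columns=[f"e{i}" for i in range(10)])
    corr, _ = partners.pairwise_correlations(m)
    assert corr[("a", "b")] == pytest.approx(1.0)
    assert corr[("a", "c")] == pytest.approx(-1.0)


def test_matches_naive_pearson_oracle():
    m = _random_matrix(5)
    corr, _ = partners.pairwise_correlations(m)
    for a, b in itertools.combinations(m.index, 2):
        expected = naive_pearson(m.loc[a].tolist(), m.loc[b].tolist())
        assert corr[(a, b)] == pytest.approx(expected, abs=1e-12)


def test_constant_genes_excluded_with_report():
    m = _random_matrix(4)
    m.loc["flat"] = 2.0
    corr, excluded = partners.pairwise_correlations(m)
    assert excluded == ["flat"]
    with pytest.raises(ValueError):
        partners.pairwise_correlations(m.loc[["flat", "g0"]].iloc[[0]])


def test_block_computation_matches_dense():
    m = _random_matrix(40)
    dense = np.corrcoef(m.to_numpy())
    blocked = partners.correlation_block(m, block_size=7).to_numpy()
    assert np.allclose(dense, blocked, atol=1e-12)


def test_permutation_preserves_value_multisets_and_is_seeded():
    m = _random_matrix(20)
    n1 = partners.permutation_null(m, seed=3)
    n2 = partners.permutation_null(m, seed=3)
    pd.testing.assert_series_equal(n1, n2)
    # permuting rows preserves each gene's value multiset: verify via re-permutation
    rng = np.random.default_rng(3)
    values = m.to_numpy().copy()
    for i in range(values.shape[0]):
        rng.shuffle(values[i])
    assert np.allclose(np.sort(values, axis=1), np.sort(m.to_numpy(), axis=1))


def test_permutation_null_mean_near_zero():
    m = _random_matrix(300, seed=5)
    r = partners.permutation_null(m, seed=1, n_pairs=10_000)
    assert abs(np.mean(r)) < 0.02


def test_distribution_enrichment_identity_and_masking():
    rng = np.random.default_rng(0)
    sample = rng.uniform(-0.5, 0.5, 50_000)
    table, p = partners.distribution_enrichment(sample, sample)
    unmasked = table.loc[~table["masked"], "ratio"]
    assert np.allclose(unmasked, 1.0)
    assert (table.loc[table["masked"], ["fraction_real", "fraction_reference"]].min(axis=1) < 8e-5).all()
    with pytest.raises(ValueError):
        partners.distribution_enrichment(np.array([]), sample)


def test_partner_edge_rule_is_strict():
    corr = pd.Series(
        [0.75, 0.70, 0.69],
        index=pd.MultiIndex.from_tuples(
            [("a", "b"), ("a", "c"), ("b", "c")], names=["gene_a", "gene_b"]
        ),
    )
    graph = partners.build_partner_graph(corr, cutoff=0.7)
    assert len(graph.edges) == 1
    assert tuple(graph.edges.loc[0, ["gene_a", "gene_b"]]) == ("a", "b")
    assert graph.partner_counts["a"] == 1 and graph.partner_counts["b"] == 1


def test_mean_of_method_cutoffs():
    assert np.mean([0.6, 0.8]) == pytest.approx(0.7)


def test_partner_graph_is_symmetric():
    m = _random_matrix(30, seed=2)
    corr, _ = partners.pairwise_correlations(m)
    g = partners.build_partner_graph(corr, cutoff=0.2).to_networkx()
    for a, b in g.edges:
        assert g.has_edge(b, a)
        assert not g.has_edge(a, a)


def test_planted_module_forms_complete_subgraph_at_zero_noise():
    cfg = SyntheticConfig(
        n_genes=60, n_entities=30, n_fluid_entities=3, n_cell_entities=4, n_rna_entities=10,
        n_modules=1, module_gene_counts=(12,), module_within_correlation=1.0,
        sample_noise_sigma=0.0, zero_dropout_rate=0.0, sources_overlap_fraction=1.0,
        tissue_specific_fraction=0.0, housekeeping_fraction=0.0, seed=4,
    )
    sources, meta, alias, truth = generate_proteome_sources(cfg)
    aggregated, _ = ingest.aggregate_sources(sources, alias)
    em, _ = integrate.integrate_sources(aggregated, {t.name: t.unit for t in sources}, meta)
    log_m, _ = profiles.log_shift(em.normal())
    module = sorted(g for g, m in truth.module_assignment.items() if m == 0)
    corr, _ = partners.pairwise_correlations(log_m, genes=module)
    graph = partners.build_partner_graph(corr, cutoff=0.7)
    assert len(graph.edges) == len(module) * (len(module) - 1) // 2


def test_and_metric_support_counting():
    m = pd.DataFrame(
        [[1, 1, 1, 0, 0], [1, 1, 0, 0, 0], [0, 0, 0, 1, 1]],
        index=["a", "b", "c"],
        columns=list("vwxyz"),
        dtype=float,
    )
    assert partners.and_metric(m, "a", "b") == 2  # A superset: |support(B)|
    assert partners.and_metric(m, "a", "c") == 0  # disjoint supports
    assert partners.and_metric(m, "a", "a") == 3
    with pytest.raises(KeyError):
        partners.and_metric(m, "a", "nope")


def test_cutoff_diagnostics_monotone_with_extremes():
    m = _random_matrix(25, seed=7)
    corr, _ = partners.pairwise_correlations(m)
    diag = partners.cutoff_diagnostics(corr, [-1.0, 0.0, 0.5, 0.9, 1.0 + 1e-9])
    assert diag.loc[0, "n_edges"] == 25 * 24 // 2  # cutoff -1: complete graph
    assert diag.iloc[-1]["n_edges"] == 0  # cutoff > 1: empty
    assert (np.diff(diag["n_edges"]) <= 0).all()
    assert (np.diff(diag["gene_coverage"]) <= 0).all()
    assert (np.diff(diag["mean_partner_count"]) <= 0).all()
    with pytest.raises(ValueError):
        partners.cutoff_diagnostics(corr, [])
    knees = partners.knee_points(diag)
    assert set(knees) == {"gene_coverage", "mean_partner_count"}


def test_pair_set_enrichment_against_background():
    rng = np.random.default_rng(8)
    n, t = 80, 40
    shared = rng.normal(0, 1, t)
    values = rng.normal(0, 1, (n, t))
    values[:20] = shared + rng.normal(0, 0.35, (20, t))  # correlated block
    m = pd.DataFrame(values, index=[f"g{i}" for i in range(n)], columns=[f"e{j}" for j in range(t)])
    corr, _ = partners.pairwise_correlations(m)
    module_pairs = set(itertools.combinations([f"g{i}" for i in range(20)], 2))
    table, p = partners.pair_set_enrichment(corr, module_pairs, min_fraction=1e-6)
    high = table[(table["bin_low"] >= 0.5) & ~table["masked"]]
    assert p < 0.05 and (high["ratio"].dropna() > 1).all()
    # all pairs as the set: every unmasked ratio is 1
    all_pairs = set(map(tuple, corr.index))
    t_all, _ = partners.pair_set_enrichment(corr, all_pairs, min_fraction=1e-9)
    assert np.allclose(t_all["ratio"].dropna(), 1.0)
    # uncorrelated pairs: no significant enrichment
    rand_pairs = set(itertools.combinations([f"g{i}" for i in range(20, 60)], 2))
    _, p_rand = partners.pair_set_enrichment(corr, rand_pairs, min_fraction=1e-6)
    assert p_rand > 0.05
    with pytest.raises(ValueError):
        partners.pair_set_enrichment(corr, {("x1", "x2")})
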