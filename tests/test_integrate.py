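"""PPM conversion, sample filters, geometric-mean averaging, entity matrix."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protatlas import ingest, integrate
from protatlas.config import SyntheticConfig
from protatlas.synthetic import generate_proteome_sources


def test_ibaq_to_ppm_formula():
    out = integrate.ibaq_to_ppm(np.array([2.0, 3.0, 5.0]))
    assert np.allclose(out, [200_000, 300_000, 500_000])


def test_ibaq_to_ppm_single_gene():
    assert integrate.ibaq_to_ppm(np.array([7.3]))[0] == pytest.approx(1e6)


def test_ibaq_to_ppm_all_zero_errors():
    with pytest.raises(ValueError):
        integrate.ibaq_to_ppm(np.zeros(4))


def test_ppm_passthrough():
    wide = pd.DataFrame({"s1": [1.0, 2.0]}, index=["a", "b"])
    assert integrate.to_ppm(wide, "PPM") is wide


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(min_value=0, max_value=1e9), min_size=1, max_size=50).filter(lambda v: sum(v) > 0))
def test_ppm_columns_sum_to_a_million(values):
    out = integrate.ibaq_to_ppm(np.array(values))
    assert out.sum() == pytest.approx(1e6, rel=1e-6)


def test_filter_min_gene_boundary():
    genes = [f"g{i}" for i in range(12)]
    wide = pd.DataFrame(0.0, index=genes, columns=["nine", "ten"])
    wide.loc[genes[:9], "nine"] = 1.0
    wide.loc[genes[:10], "ten"] = 1.0
    kept, report = integrate.filter_samples(wide, min_genes=10)
    assert list(kept.columns) == ["ten"]
    assert report.loc[0, "sample_id"] == "nine"


def test_filter_collapses_exact_duplicates():
    wide = pd.DataFrame(
        {"a": np.arange(12.0) + 1, "b": np.arange(12.0) + 1, "c": np.arange(12.0) + 2}
    )
    kept, report = integrate.filter_samples(wide, min_genes=10)
    assert list(kept.columns) == ["a", "c"]
    assert (report["reason"] == "exact duplicate").sum() == 1


@pytest.mark.parametrize(
    "values,expected",
    [((100.0, 400.0), 200.0), ((100.0, 0.0, 400.0), 200.0), ((0.0, 0.0), 0.0)],
)
def test_geometric_mean_skips_zeros(values, expected):
    out = integrate.gm_nonzero(np.array([values]), axis=1)
    assert out[0] == pytest.approx(expected)


def test_preaverage_duplicates_groups():
    wide = pd.DataFrame(
        {"s1": [100.0, 0.0], "s2": [400.0, 8.0], "s3": [3.0, 5.0]}, index=["g1", "g2"]
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "source_name": ["x", "x", "y"],
            "entity": ["liver", "liver", "liver"],
            "category": ["normal tissue"] * 3,
            "duplicate_group": ["d1", "d1", "d2"],
        }
    )
    grouped, gmeta = integrate.preaverage_duplicates(wide, meta)
    assert grouped.loc["g1", "d1"] == pytest.approx(200.0)  # gm of non-zeros
    assert grouped.loc["g2", "d1"] == pytest.approx(8.0)  # zero ignored
    assert grouped.loc["g1", "d2"] == pytest.approx(3.0)
    assert set(gmeta["sample_id"]) == {"d1", "d2"}


def _meta(cols, entity):
    return pd.DataFrame(
        {
            "sample_id": cols,
            "source_name": ["x"] * len(cols),
            "entity": [entity] * len(cols),
            "category": ["normal tissue"] * len(cols),
        }
    )


def test_average_entities_gm_and_single_sample_identity():
    wide = pd.DataFrame(
        {"s1": [10.0, 1.0], "s2": [1000.0, 2.0], "s3": [0.0, 4.0]}, index=["g1", "g2"]
    )
    em = integrate.average_entities(wide, _meta(["s1", "s2", "s3"], "liver"))
    assert em.matrix.loc["g1", "liver"] == pytest.approx(100.0)  # gm of the 2 non-zeros
    single = integrate.average_entities(wide[["s1"]], _meta(["s1"], "liver"))
    assert np.allclose(single.matrix["liver"], wide["s1"])


def test_average_entities_excludes_high_gene_count_datasets():
    n = 12_500
    rng = np.random.default_rng(0)
    big = rng.uniform(1, 10, n)  # 12,500 mapped genes: excluded from averaging
    small = np.zeros(n)
    small[:100] = 5.0
    wide = pd.DataFrame({"big": big, "small": small}, index=[f"g{i}" for i in range(n)])
    with pytest.warns(UserWarning, match="excluded from averaging"):
        em = integrate.average_entities(wide, _meta(["big", "small"], "liver"))
    assert np.allclose(em.matrix["liver"], small)


def test_average_entities_order_invariant_and_matches_naive_loop():
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(20)]
    cols = [f"s{i}" for i in range(6)]
    values = rng.uniform(0, 50, (20, 6))
    values[rng.random((20, 6)) < 0.3] = 0.0
    wide = pd.DataFrame(values, index=genes, columns=cols)
    meta = pd.DataFrame(
        {
            "sample_id": cols,
            "source_name": ["x"] * 6,
            "entity": ["e1", "e1", "e2", "e2", "e2", "e3"],
            "category": ["normal tissue"] * 6,
        }
    )
    em = integrate.average_entities(wide, meta)
    # naive per-cell loop oracle
    for ent, sids in [("e1", cols[:2]), ("e2", cols[2:5]), ("e3", cols[5:])]:
        for g in genes:
            vals = [wide.loc[g, s] for s in sids if wide.loc[g, s] > 0]
            expected = float(np.prod(vals)) ** (1 / len(vals)) if vals else 0.0
            assert em.matrix.loc[g, ent] == pytest.approx(expected, rel=1e-9)
    perm = list(rng.permutation(cols))
    em2 = integrate.average_entities(wide[perm], meta)
    pd.testing.assert_frame_equal(em.matrix, em2.matrix)


def test_zero_noise_pipeline_recovers_planted_profile():
    """With no noise, full overlap and no dropout, every entity column equals
    the planted profile."""
    cfg = SyntheticConfig(
        n_genes=100, n_entities=25, n_fluid_entities=3, n_cell_entities=4,
        n_rna_entities=10, seed=9, sample_noise_sigma=0.0, zero_dropout_rate=0.0,
        sources_overlap_fraction=1.0,
    )
    sources, meta, alias, truth = generate_proteome_sources(cfg)
    aggregated, _ = ingest.aggregate_sources(sources, alias)
    units = {t.name: t.unit for t in sources}
    em, _ = integrate.integrate_sources(aggregated, units, meta)
    got = em.normal()[truth.entity_profile.columns].loc[truth.entity_profile.index]
    rel = np.abs(got.to_numpy() - truth.entity_profile.to_numpy())
    denom = np.where(truth.entity_profile.to_numpy() > 0, truth.entity_profile.to_numpy(), 1.0)
    assert (rel / denom).max() < 1e-9


def test_entity_matrix_roundtrip_and_normal_subset(tmp_path, entity_matrix):
    entity_matrix.write(tmp_path / "em")
    back = integrate.EntityMatrix.read(tmp_path / "em")
    pd.testing.assert_frame_equal(back.matrix, entity_matrix.matrix)
    assert back.entity_meta == entity_matrix.entity_meta
    normal_cats = set(integrate.EntityMatrix.NORMAL_CATEGORIES)
    assert all(
        entity_matrix.entity_meta[c] in normal_cats for c in entity_matrix.normal().columns
    )
    assert any(v == "cell line" for v in entity_matrix.entity_meta.values())
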