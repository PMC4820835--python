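"""Integrate the mined sources into the gene x anatomical-entity PPM matrix.

Symbolizes identifiers, aggregates protein rows to genes, converts iBAQ
samples to PPM, filters small/duplicate samples, pre-averages duplicate
curations, and averages across sources per entity (geometric mean of
non-zero PPM).  Writes the matrix artifact under scratch/ and an
integration summary under results/.
"""

import pandas as pd

from common import ARTIFACTS, INPUTS, RESULTS, ensure_dirs, require, study_config
from protatlas import ingest, integrate, profiles


def main() -> None:
    ensure_dirs()
    require(INPUTS / "sample_meta.tsv", "analysis/01_simulate_inputs.py")
    ARTIFACTS.mkdir(parents=True, exist_ok=True)
    cfg = study_config()

    tables = [ingest.read_source_table(p) for p in sorted(INPUTS.glob("source_*.tsv"))]
    alias = ingest.read_alias_map(INPUTS / "aliases.tsv")
    meta = ingest.read_sample_meta(INPUTS / "sample_meta.tsv")
    aggregated, rejects = ingest.aggregate_sources(tables, alias)
    em, exclusions = integrate.integrate_sources(
        aggregated,
        {t.name: t.unit for t in tables},
        meta,
        min_genes=cfg.min_genes_per_sample,
        max_gene_count=cfg.max_gene_count,
    )
    em.write(ARTIFACTS / "entity_matrix")

    normal = em.normal()
    breadth = profiles.expression_breadth(normal)
    summary = pd.DataFrame(
        {
            "metric": [
                "genes",
                "entities_total",
                "entities_normal",
                "samples_excluded",
                "rows_rejected",
                "median_expression_breadth",
                "zero_fraction",
            ],
            "value": [
                em.matrix.shape[0],
                em.matrix.shape[1],
                normal.shape[1],
                len(exclusions),
                len(rejects),
                breadth.median(),
                float((normal == 0).to_numpy().mean()),
            ],
        }
    )
    summary.to_csv(RESULTS / "02_integration_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"\nentity matrix ({em.matrix.shape[0]} genes x {em.matrix.shape[1]} entities) -> {ARTIFACTS}")


if __name__ == "__main__":
    main()
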