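"""Shared fixtures: synthetic study data at the default conditions, plus a
reduced configuration for fast end-to-end runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from protatlas import ingest, integrate, synthetic
from protatlas.config import PipelineConfig, SyntheticConfig

TINY_KWARGS = dict(
    n_genes=80,
    n_entities=24,
    n_fluid_entities=3,
    n_cell_entities=4,
    n_rna_entities=10,
    n_modules=2,
    module_gene_counts=(8, 8),
    seed=11,
)


@pytest.fixture(scope="session")
def study():
    """Default-condition synthetic study (sources, meta, aliases, truth)."""
    cfg = SyntheticConfig(n_genes=250, seed=1)
    sources, meta, alias, truth = synthetic.generate_proteome_sources(cfg)
    return cfg, sources, meta, alias, truth


@pytest.fixture(scope="session")
def entity_matrix(study):
    """Integrated entity matrix for the default-condition study."""
    _, sources, meta, alias, _ = study
    aggregated, _ = ingest.aggregate_sources(sources, alias)
    units = {t.name: t.unit for t in sources}
    ematrix, _ = integrate.integrate_sources(aggregated, units, meta)
    return ematrix


@pytest.fixture(scope="session")
def tiny_config():
    return PipelineConfig(seed=11, synthetic=SyntheticConfig(**TINY_KWARGS))


# ---------------------------------------------------------------------------
# Independent oracles (never used by the implementation)


def naive_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Two-pass textbook Pearson correlation."""
    mx, my = sum(x) / len(x), sum(y) / len(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x) ** 0.5
    dy = sum((b - my) ** 2 for b in y) ** 0.5
    return num / (dx * dy)


def naive_ward_linkage(dist: np.ndarray) -> np.ndarray:
    """O(n^3) agglomerative Ward clustering via the Lance-Williams recurrence.

    ``dist`` is a square matrix of base distances between singletons.
    Returns a (n-1, 4) linkage matrix in scipy convention.
    """
    n = dist.shape[0]
    d2 = dist.astype(float) ** 2
    active = {i: (i, 1) for i in range(n)}  # slot -> (cluster id, size)
    d2 = d2.copy()
    link = []
    next_id = n
    slots = list(range(n))
    while len(slots) > 1:
        best = None
        for ii in range(len(slots)):
            for jj in range(ii + 1, len(slots)):
                a, b = slots[ii], slots[jj]
                if best is None or d2[a, b] < best[0]:
                    best = (d2[a, b], a, b)
        _, a, b = best
        ida, na = active[a]
        idb, nb = active[b]
        h = np.sqrt(d2[a, b])
        link.append([min(ida, idb), max(ida, idb), h, na + nb])
        for c in slots:
            if c in (a, b):
                continue
            _, nc = active[c]
            val = (
                (na + nc) * d2[a, c] + (nb + nc) * d2[b, c] - nc * d2[a, b]
            ) / (na + nb + nc)
            d2[a, c] = d2[c, a] = val
        active[a] = (next_id, na + nb)
        next_id += 1
        slots.remove(b)
    return np.asarray(link)


def brute_silhouette(dist: np.ndarray, labels: np.ndarray) -> float:
    """Textbook mean silhouette from a full distance matrix."""
    n = len(labels)
    scores = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = np.mean([dist[i, j] for j in own])
        b = min(
            np.mean([dist[i, j] for j in range(n) if labels[j] == lab])
            for lab in set(labels)
            if lab != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))
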