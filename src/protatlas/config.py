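"""Configuration objects for the synthetic generator and the pipeline."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must be in [0, 1], got {value}")


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic multi-source proteome generator.

    Defaults emulate the salient properties of the mined inputs: four
    sources with ~47% four-way gene overlap, per-sample log10-abundance
    distributions spanning several orders of magnitude, duplicate
    curations of the same experiment, planted co-expression modules,
    tissue-specific and housekeeping genes, and RNA vectors with
    configurable per-gene protein/RNA copy ratio and correlation.
    """

    n_genes: int = 400
    n_entities: int = 69
    n_sources: int = 4
    #: fraction of genes reported by every source (the all-way overlap)
    sources_overlap_fraction: float = 0.47
    #: curation tables emitted per (source, entity) experiment
    n_duplicate_curations: int = 2
    #: (mu, sigma) of the per-gene baseline log10 PPM level
    lognormal_mu_sigma: tuple[float, float] = (1.5, 1.0)
    n_modules: int = 3
    module_gene_counts: tuple[int, ...] | None = None
    #: target within-module Pearson correlation; module profiles are a
    #: correlated decomposition of the same per-entity variance all genes
    #: carry, so planted modules leave per-sample marginals log-normal
    module_within_correlation: float = 0.9
    tissue_specific_fraction: float = 0.10
    #: planted spike factor for tissue-specific genes
    tissue_specific_factor: float = 10.0
    housekeeping_fraction: float = 0.05
    housekeeping_level_ppm: float = 10_000.0
    #: allowed range of planted protein/RNA copy-number ratios
    pr_ratio_range: tuple[float, float] = (1e2, 1e6)
    #: log10 mean/sd of planted P/R ratios (log-normal across genes)
    pr_ratio_log10_mu_sigma: tuple[float, float] = (3.77, 0.8)
    #: planted protein-RNA correlation targets, assigned round-robin
    pr_correlation_levels: tuple[float, ...] = (0.2, 0.5, 0.8)
    zero_dropout_rate: float = 0.02
    #: sd of per-gene per-entity log10 deviation around the baseline
    entity_effect_sigma: float = 0.5
    #: sd of per-sample multiplicative measurement noise (log10)
    sample_noise_sigma: float = 0.2
    #: sd of per-individual RNA measurement noise (log10, mean-one)
    rna_noise_sigma: float = 0.2
    n_rna_entities: int = 24
    n_rna_individuals: int = 5
    n_fluid_entities: int = 6
    n_cell_entities: int = 8
    n_cell_line_entities: int = 2
    #: fraction of gene pairs sharing a multi-gene protein in the alias map
    shared_protein_fraction: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ConfigError("n_genes must be >= 2")
        if self.n_entities < 2:
            raise ConfigError("n_entities must be >= 2")
        if self.n_sources < 1:
            raise ConfigError("n_sources must be >= 1")
        for name in (
            "sources_overlap_fraction",
            "tissue_specific_fraction",
            "housekeeping_fraction",
            "zero_dropout_rate",
            "shared_protein_fraction",
        ):
            _check_fraction(name, getattr(self, name))
        _check_fraction("module_within_correlation", self.module_within_correlation)
        # JSON round-trips turn tuples into lists; coerce back
        for name in (
            "lognormal_mu_sigma",
            "pr_ratio_range",
            "pr_ratio_log10_mu_sigma",
            "pr_correlation_levels",
        ):
            setattr(self, name, tuple(getattr(self, name)))
        for rho in self.pr_correlation_levels:
            if not (-1.0 <= rho <= 1.0):
                raise ConfigError(f"pr_correlation_levels must be in [-1, 1], got {rho}")
        if self.module_gene_counts is None:
            self.module_gene_counts = tuple([max(2, self.n_genes // 15)] * self.n_modules)
        else:
            self.module_gene_counts = tuple(self.module_gene_counts)
        if len(self.module_gene_counts) != self.n_modules:
            raise ConfigError("module_gene_counts length must equal n_modules")
        if sum(self.module_gene_counts) > self.n_genes:
            raise ConfigError("module gene counts exceed n_genes")
        if self.n_fluid_entities + self.n_cell_entities >= self.n_entities:
            raise ConfigError("fluid + cell entity counts must be < n_entities")
        if self.n_rna_entities > self.n_entities - self.n_fluid_entities - self.n_cell_entities:
            raise ConfigError("n_rna_entities exceeds available tissue entities")
        lo, hi = self.pr_ratio_range
        if not (0 < lo <= hi):
            raise ConfigError("pr_ratio_range must be positive and ordered")


@dataclass
class PipelineConfig:
    """Parameters of the full integration and annotation pipeline."""

    de_cutoff: float = 6.0
    abundance_floor: float = 0.1
    partner_cutoff: float = 0.7
    rna_de_cutoff: float = 4.0
    protein_copy_factor: float = 1e4
    rna_copy_factor: float = 1.0
    min_genes_per_sample: int = 10
    max_gene_count: int = 12_000
    root_scale_exponent: float = 4.0
    kmeans_k_grid: tuple[int, ...] = tuple(range(2, 11))
    kmeans_repeats: int = 10
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self) -> None:
        for name in (
            "de_cutoff",
            "abundance_floor",
            "rna_de_cutoff",
            "protein_copy_factor",
            "rna_copy_factor",
            "root_scale_exponent",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not (-1.0 < self.partner_cutoff < 1.0):
            raise ConfigError("partner_cutoff must be in (-1, 1)")
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticConfig(**self.synthetic)
        self.kmeans_k_grid = tuple(self.kmeans_k_grid)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yml", ".yaml"}:
            import yaml

            return cls(**yaml.safe_load(text))
        return cls.from_json(text)
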