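"""Shared paths and the default study configuration for the analysis scripts.

The bulky intermediates (simulated source tables, the full entity matrix)
live under scratch/; the small summary tables each script reports go to
results/.
"""

from pathlib import Path

from protatlas.config import PipelineConfig, SyntheticConfig

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"
INPUTS = SCRATCH / "inputs"
ARTIFACTS = SCRATCH / "artifacts"

SEED = 1


def study_config() -> PipelineConfig:
    """Default study conditions: 400 genes, 69 normal entities, 4 sources."""
    return PipelineConfig(seed=SEED, synthetic=SyntheticConfig(n_genes=400, seed=SEED))


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)


def require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise SystemExit(f"missing {path}; run {producer} first")
    return path
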