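"""Pipeline configuration.

Every stage's tunables are grouped in a pydantic model; unknown keys are
rejected and the fully resolved configuration (defaults filled in) is
written alongside the outputs for reproducibility. A single global seed
is expanded into independent per-stage substreams.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["PipelineConfig", "stage_seed"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    n_samples: int = 142
    layer_sizes: list[int] = Field(default=[118, 97, 46, 125, 116, 65, 104])
    layer_groups: list[int] = Field(default=[2, 2, 2, 2, 2, 2, 3])
    effect_size: float = 2.0
    noise_sd: float = 1.0
    total_genes: int = 2000
    subtype_props: dict[str, float] = Field(
        default={"CIN": 0.542, "MSI": 0.190, "GS": 0.205, "EBV": 0.063}
    )
    subtype_layers: tuple[int, int] = (0, 1)
    unlabeled_fraction: float = 0.38  # subtype hidden in the clinical table
    missing_rate: float = 0.02
    survival_layer: int = 0
    log_hazard_ratios: list[float] = Field(default=[0.0, 1.1])
    baseline_rate: float = 0.012
    censor_rate: float = 0.055


class PreprocessConfig(_Strict):
    pre_logged: bool = True
    log2_offset: float = 1.0
    min_valid_fraction: float = 0.75
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    top_n: int = 2000


class AssignConfig(_Strict):
    fdr: float = 0.05
    n_permutations: int = 100
    panel: str = "sam"  # "sam" (significant set) or "all" (whole working set)


class NetworkConfig(_Strict):
    max_added_edges: int = 200
    max_branch_size: int = 250
    min_branch_size: int = 3
    n_branches: int | None = None
    enrichment_q: float = 0.05
    all_branch_genes: bool = False


class LayersConfig(_Strict):
    max_layers: int = 7
    k_range: list[int] = Field(default=[2, 3, 4])
    stop_pac: float = 0.4
    sparsity: float | None = None  # None = tune by permutation gap
    n_resample: int = 500
    p_sample: float = 0.8
    n_starts: int = 5
    n_tune_permutations: int = 6
    weight_threshold_frac: float = 1e-4
    min_pool: int = 20


class CmlConfig(_Strict):
    include_layers: list[int] = Field(default=[1, 2, 4, 5])
    k_range: list[int] = Field(default=[2, 3, 4])
    n_resample: int = 500
    p_sample: float = 0.8
    redundancy_warn: float = 0.7


class SurviveConfig(_Strict):
    pairwise: bool = False
    plots: bool = False


class PipelineConfig(_Strict):
    """Top-level configuration: one block per stage plus globals."""

    seed: int = 0
    outdir: str = "gclayers_out"
    stages: list[str] = Field(
        default=["simulate", "preprocess", "assign", "network", "layers", "cml", "survive"]
    )
    log_level: str = "INFO"
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    assign: AssignConfig = Field(default_factory=AssignConfig)
    network: NetworkConfig = Field(default_factory=NetworkConfig)
    layers: LayersConfig = Field(default_factory=LayersConfig)
    cml: CmlConfig = Field(default_factory=CmlConfig)
    survive: SurviveConfig = Field(default_factory=SurviveConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        )


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream below 2^31."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)
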