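"""Pipeline configuration: one YAML document, strictly validated.

Unknown keys are rejected; every stochastic stage draws from the single
top-level seed (stage generators are spawned deterministically from it).
The effective configuration round-trips losslessly through
``serialize``/``parse``.
"""

from __future__ import annotations

import hashlib

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .simulate import FOUNDER_NAMES

__all__ = [
    "MapConfig",
    "FounderConfig",
    "LineConfig",
    "QtlConfig",
    "TraitConfig",
    "ExperimentConfig",
    "SimulatorConfig",
    "AnalysisConfig",
    "PipelineConfig",
    "parse",
    "serialize",
    "config_hash",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MapConfig(_Strict):
    n_markers: int = 1345
    n_chromosomes: int = 12
    total_cM: float = 2156.0
    bp_per_cM: float = 420_000.0


class FounderConfig(_Strict):
    diversity: float = 1.0
    n_genes_per_chrom: int = 40
    n_variants_per_gene_region: int = 10
    gene_flank_bp: int = 2000
    names: list[str] = Field(default_factory=lambda: list(FOUNDER_NAMES))


class LineConfig(_Strict):
    n_lines: int = 250
    n_selfing_generations: int = 3
    fixed_funnel: bool = False
    genotyping_error: float = 0.0


class QtlConfig(_Strict):
    chrom: str
    position_cM: float
    effects: list[float]
    treatment_scale: dict[str, float] = Field(default_factory=dict)


class TraitConfig(_Strict):
    trait: str
    qtls: list[QtlConfig] = Field(default_factory=list)
    mu: float = 0.0
    treatment_offsets: dict[str, float] = Field(default_factory=dict)
    target_h2: float | None = None
    residual_var: float | dict[str, float] | None = None
    n_replicates: int = 2
    transform: str = "identity"


class ExperimentConfig(_Strict):
    name: str
    treatments: list[str]
    traits: list[TraitConfig]


class SimulatorConfig(_Strict):
    map: MapConfig = Field(default_factory=MapConfig)
    founders: FounderConfig = Field(default_factory=FounderConfig)
    lines: LineConfig = Field(default_factory=LineConfig)
    experiments: list[ExperimentConfig] = Field(default_factory=list)


class AnalysisConfig(_Strict):
    error_rate: float = 0.01
    grid_step_cM: float = 2.0
    n_meioses: float | None = None  # default: funnel + selfing expectation
    assignment_threshold: float = 0.5
    lod_threshold: float = 3.0
    r_mode: str = "arithmetic"  # replicate averaging for h2
    mv_paired: bool = True
    map_plasticity: bool = True
    max_ci_mb: float = 2.0  # candidate filtering only below this CI size
    groupings: dict[str, str] = Field(default_factory=dict)  # trait -> pattern
    suggest_groupings: bool = True


class PipelineConfig(_Strict):
    seed: int = 0
    simulate: SimulatorConfig = Field(default_factory=SimulatorConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)


def parse(text: str) -> PipelineConfig:
    payload = yaml.safe_load(text) or {}
    return PipelineConfig.model_validate(payload)


def serialize(config: PipelineConfig) -> str:
    return yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)


def config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(serialize(config).encode()).hexdigest()
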