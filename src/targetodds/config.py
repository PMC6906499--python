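"""Scenario configuration: typed, validated, round-trippable.

A scenario file (YAML or JSON) describes the sample space, the per-stage
error rates, the simulation settings and output formatting.  Every field has
a default equal to the base case — 20,000 protein-coding genes, 10,000
diseases, 4,000 druggable genes, 100 causal genes per disease, power 0.8 in
both stages, alpha 0.05 (orthodox mode) or 5e-8 (genomic mode) preclinically
and 0.05 clinically — so an empty file is a complete, valid configuration.
Unknown keys are rejected with field-path-qualified messages.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import SampleSpace, TestParams
from .simulate import SimulationConfig
from .two_stage import StageParams

__all__ = ["ScenarioConfig", "load_config", "dump_config"]

GWAS_ALPHA = 5e-8


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SpaceSection(_Strict):
    n_genes: int = Field(default=20_000, gt=0)
    n_diseases: int = Field(default=10_000, gt=0)
    n_druggable: int = Field(default=4_000, gt=0)
    causal_per_disease: float = Field(default=100.0, ge=0)

    @model_validator(mode="after")
    def _bounds(self) -> "SpaceSection":
        if self.n_druggable > self.n_genes:
            raise ValueError("space.n_druggable cannot exceed space.n_genes")
        if self.causal_per_disease > self.n_genes:
            raise ValueError("space.causal_per_disease cannot exceed space.n_genes")
        return self

    def to_sample_space(self) -> SampleSpace:
        return SampleSpace(
            n_genes=self.n_genes,
            n_diseases=self.n_diseases,
            n_druggable=self.n_druggable,
            causal_per_disease=self.causal_per_disease,
        )


class StagesSection(_Strict):
    mode: str = Field(default="orthodox", pattern="^(orthodox|genomic)$")
    alpha_pc: float | None = Field(default=None, ge=0, le=1)
    beta_pc: float = Field(default=0.2, ge=0, le=1)
    alpha_c: float = Field(default=0.05, ge=0, le=1)
    beta_c: float = Field(default=0.2, ge=0, le=1)

    @property
    def effective_alpha_pc(self) -> float:
        if self.alpha_pc is not None:
            return self.alpha_pc
        return 0.05 if self.mode == "orthodox" else GWAS_ALPHA

    def to_stage_params(self, gamma_pc: float) -> StageParams:
        return StageParams(
            preclinical=TestParams(
                alpha=self.effective_alpha_pc, beta=self.beta_pc, gamma=gamma_pc
            ),
            clinical_alpha=self.alpha_c,
            clinical_beta=self.beta_c,
        )


class SimulationSection(_Strict):
    replicates: int = Field(default=1, ge=1)
    seed: int = 0
    mode: str = Field(default="fixed-count", pattern="^(fixed-count|bernoulli)$")

    def to_simulation_config(self) -> SimulationConfig:
        return SimulationConfig(replicates=self.replicates, seed=self.seed, mode=self.mode)


class OutputSection(_Strict):
    format: str = Field(default="json", pattern="^(json|csv)$")
    precision: dict[str, int] = Field(default_factory=dict)


class SweepSection(_Strict):
    label: str = ""
    overrides: dict[str, float] = Field(default_factory=dict)


class ScenarioConfig(_Strict):
    space: SpaceSection = Field(default_factory=SpaceSection)
    stages: StagesSection = Field(default_factory=StagesSection)
    sweeps: list[SweepSection] = Field(default_factory=list)
    simulation: SimulationSection = Field(default_factory=SimulationSection)
    output: OutputSection = Field(default_factory=OutputSection)


def load_config(path: str | Path | None = None) -> ScenarioConfig:
    """Load and validate a scenario file; ``None`` or an empty file gives defaults."""
    if path is None:
        return ScenarioConfig()
    raw = Path(path).read_text()
    data = yaml.safe_load(raw)  # YAML superset also parses JSON
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return ScenarioConfig.model_validate(data)


def dump_config(cfg: ScenarioConfig, path: str | Path) -> None:
    """Write a config back to YAML; ``load_config`` round-trips it exactly."""
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
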