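"""YAML configuration schema for simulation and sweep runs.

The schema is validated with pydantic so a malformed file fails with a
field-level message before any computation starts.  Top-level keys:

``seed``
    Parent seed; per-replicate streams are derived from it.
``scenarios``
    List of scenario blocks (see :class:`ScenarioModel`).
``sweep``
    Optional degree-sweep block applied to the first scenario that has both
    an SRS and a DSS design.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from .popgen import INCOME_COEFS, RACE_LABELS, RACE_PROBS, TRUST_COEFS, PopulationConfig
from .simulation import DesignSpec, MisclassSpec, Scenario


class PopulationModel(BaseModel):
    size: int = 100_000
    race_probs: list[float] = Field(default_factory=lambda: list(RACE_PROBS))
    trust_coefs: list[float] = Field(default_factory=lambda: list(TRUST_COEFS))
    income_coefs: list[float] = Field(default_factory=lambda: list(INCOME_COEFS))
    labels: list[str] = Field(default_factory=lambda: list(RACE_LABELS))

    def build(self) -> PopulationConfig:
        return PopulationConfig(
            N=self.size,
            race_probs=tuple(self.race_probs),
            trust_coefs=tuple(self.trust_coefs),
            income_coefs=tuple(self.income_coefs),
            labels=tuple(self.labels),
        )


class MisclassModel(BaseModel):
    kind: Literal[
        "none", "empirical_overall", "empirical_differential", "degree"
    ] = "none"
    degree: Optional[float] = None
    pattern: Literal["uniform", "table_proportional"] = "uniform"
    interpretation: Literal["direct", "bayes_inverted"] = "bayes_inverted"

    @field_validator("degree")
    @classmethod
    def _degree_range(cls, v):
        if v is not None and not 0 <= v <= 1:
            raise ValueError("degree must lie in [0, 1]")
        return v

    def build(self) -> MisclassSpec:
        return MisclassSpec(
            kind=self.kind,
            degree=self.degree,
            pattern=self.pattern,
            interpretation=self.interpretation,
        )


class DesignModel(BaseModel):
    kind: Literal["full_cohort", "srs", "dss"]
    n: Optional[int] = None
    quotas: Optional[list[int]] = None
    methods: Optional[
        list[Literal["design_agnostic", "model_based", "design_based"]]
    ] = None

    def build(self) -> DesignSpec:
        return DesignSpec(
            kind=self.kind,
            n=self.n,
            quotas=tuple(self.quotas) if self.quotas else None,
            methods=tuple(self.methods) if self.methods else None,
        )


class ScenarioModel(BaseModel):
    name: str
    reps: int = Field(default=10_000, ge=1)
    population: PopulationModel = Field(default_factory=PopulationModel)
    misclassification: MisclassModel = Field(default_factory=MisclassModel)
    designs: list[DesignModel]
    methods: list[
        Literal["design_agnostic", "model_based", "design_based"]
    ] = ["design_agnostic", "model_based", "design_based"]
    variance: Literal["unstratified", "stratified"] = "unstratified"
    ci_level: float = Field(default=0.95, gt=0, lt=1)

    def build(self, seed: int) -> Scenario:
        return Scenario(
            name=self.name,
            population=self.population.build(),
            misclassification=self.misclassification.build(),
            designs=tuple(d.build() for d in self.designs),
            methods=tuple(self.methods),
            reps=self.reps,
            seed=seed,
            ci_level=self.ci_level,
            variance=self.variance,
        )


class SweepModel(BaseModel):
    degrees: list[float]
    pattern: Literal["uniform", "table_proportional"] = "uniform"
    reps: Optional[int] = None  # override the scenario's replication count

    @field_validator("degrees")
    @classmethod
    def _nonempty(cls, v):
        if not v:
            raise ValueError("degrees list must not be empty")
        if any(not 0 <= d <= 1 for d in v):
            raise ValueError("degrees must lie in [0, 1]")
        return v


class RunConfig(BaseModel):
    seed: int = 0
    scenarios: list[ScenarioModel] = Field(default_factory=list)
    sweep: Optional[SweepModel] = None


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def example_config_path(name: str) -> Path:
    """Path to a bundled example configuration (e.g. ``"vumc_smoke"``)."""
    p = Path(__file__).parent / "configs" / f"{name}.yaml"
    if not p.exists():
        available = sorted(q.stem for q in p.parent.glob("*.yaml"))
        raise FileNotFoundError(f"no bundled config {name!r}; available: {available}")
    return p
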