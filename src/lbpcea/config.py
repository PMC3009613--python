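"""Configuration schema, loading and conversion to model objects.

One structured YAML file is the single source of truth for an analysis: the
shipped default (``lbpcea/data/default_config.yaml``) encodes the base case,
and user files are validated against the same schema — unknown keys are
rejected, probabilities are range-checked, and every block maps onto the
typed containers the engine consumes.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .cost_model import CycleCosts, VisitSchedule, VisitType, visit_schedule_cost
from .markov_engine import Conventions
from .parameters import ConfigurationError, DistributionSpec, ModelSettings
from .synthetic_data import generate_life_table

__all__ = [
    "AnalysisConfig",
    "load_config",
    "default_config",
    "dump_config",
    "config_sha256",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelBlock(_Strict):
    n_cycles: int = Field(ge=1)
    cycle_length_years: float = Field(gt=0)
    annual_discount_rate: float = Field(ge=0, lt=1)
    initial_state: Literal["acute"] = "acute"
    cohort_size: int = Field(default=10_000, ge=1)


class ConventionsBlock(_Strict):
    reward_timing: Literal["start", "end"] = "start"
    half_cycle: bool = False
    outcome_discounting: Literal["per_cycle", "none"] = "none"
    rr_scale: Literal["probability", "rate"] = "probability"
    cohort_timing: Literal["start", "end"] = "start"


class MortalityBlock(_Strict):
    kind: Literal["constant", "life_table"]
    per_cycle: Optional[float] = Field(default=None, ge=0, le=1)
    start_age: int = 60
    n_years: int = 5
    base_annual_mortality: float = 0.004
    growth_per_year: float = 0.08

    @model_validator(mode="after")
    def _check(self):
        if self.kind == "constant" and self.per_cycle is None:
            raise ValueError("constant mortality requires per_cycle")
        return self


class ParameterSpec(_Strict):
    value: float
    dist: Literal["beta", "gamma", "lognormal", "fixed"]
    a: float = 0.0
    b: float = 0.0


_PROBABILITY_PARAMS = ("tATC", "tWTC", "tCTW", "uALBP", "uCLBPUC", "uCLBPACUC", "uWell")


class VisitTypeBlock(_Strict):
    label: str
    per_visit_cost: float = Field(ge=0)
    frequency: int = Field(ge=0)


class StrategyCostBlock(_Strict):
    direct_nonmedical: float = Field(ge=0)
    visit_schedule: list[VisitTypeBlock]


class CostsBlock(_Strict):
    include_indirect: bool = False
    indirect_nonmedical_per_cycle: float = Field(ge=0)
    strategies: dict[Literal["usual_care", "collaborative"], StrategyCostBlock]


class LambdaGridBlock(_Strict):
    start: float = Field(ge=0)
    stop: float = Field(gt=0)
    step: float = Field(gt=0)


class PSABlock(_Strict):
    n_draws: int = Field(ge=1)
    seed: int = Field(ge=0)
    lambda_grid: LambdaGridBlock


class VOIBlock(_Strict):
    annual_incidence: float = Field(ge=0)
    horizon_years: int = Field(ge=0)
    discount_rate: float = Field(ge=0, lt=1)


class AnalysisConfig(_Strict):
    """Validated analysis configuration (see the shipped default for the layout)."""

    model: ModelBlock
    conventions: ConventionsBlock = ConventionsBlock()
    mortality: MortalityBlock
    parameters: dict[str, ParameterSpec]
    costs: CostsBlock
    psa: PSABlock
    voi: VOIBlock

    @model_validator(mode="after")
    def _check_probability_params(self):
        for name in _PROBABILITY_PARAMS:
            spec = self.parameters.get(name)
            if spec is not None and not 0.0 <= spec.value <= 1.0:
                raise ValueError(f"{name}: probability out of range [0, 1]: {spec.value}")
        for strategy in ("usual_care", "collaborative"):
            if strategy not in self.costs.strategies:
                raise ValueError(f"costs.strategies missing {strategy!r}")
        return self

    # ---- conversions to engine objects ------------------------------------

    def distribution_specs(self) -> dict[str, DistributionSpec]:
        out = {}
        for name, spec in self.parameters.items():
            if spec.dist == "fixed":
                out[name] = DistributionSpec("fixed", spec.value)
            else:
                out[name] = DistributionSpec(spec.dist, spec.a, spec.b)
        return out

    def fixed_specs(self) -> dict[str, DistributionSpec]:
        """Degenerate specs at the point values (collapses the PSA to the base case)."""
        return {
            name: DistributionSpec("fixed", spec.value) for name, spec in self.parameters.items()
        }

    def point_values(self) -> dict[str, float]:
        return {name: spec.value for name, spec in self.parameters.items()}

    def model_settings(self) -> ModelSettings:
        grid = self.psa.lambda_grid
        return ModelSettings(
            n_cycles=self.model.n_cycles,
            cycle_length_years=self.model.cycle_length_years,
            annual_discount_rate=self.model.annual_discount_rate,
            initial_state=self.model.initial_state,
            cohort_size=self.model.cohort_size,
            lambda_grid=np.arange(grid.start, grid.stop + grid.step / 2, grid.step),
        )

    def engine_conventions(self) -> Conventions:
        c = self.conventions
        return Conventions(
            reward_timing=c.reward_timing,
            half_cycle=c.half_cycle,
            outcome_discounting=c.outcome_discounting,
            rr_scale=c.rr_scale,
        )

    def mortality_schedule(self) -> np.ndarray:
        """Per-cycle death probabilities, one entry per model cycle."""
        n = self.model.n_cycles
        if self.mortality.kind == "constant":
            return np.full(n, float(self.mortality.per_cycle))
        table = generate_life_table(
            start_age=self.mortality.start_age,
            n_years=self.mortality.n_years,
            base_annual_mortality=self.mortality.base_annual_mortality,
            growth_per_year=self.mortality.growth_per_year,
        )
        per_cycle = table.per_cycle_probabilities(self.model.cycle_length_years)
        if len(per_cycle) < n:
            raise ConfigurationError(
                f"life table covers {len(per_cycle)} cycles but the model needs {n}"
            )
        return per_cycle[:n]

    def visit_schedule(self, strategy: str) -> VisitSchedule:
        block = self.costs.strategies[strategy]
        return VisitSchedule(
            tuple(VisitType(v.label, v.per_visit_cost, v.frequency) for v in block.visit_schedule)
        )

    def cycle_costs(self, strategy: str, include_indirect: bool | None = None) -> CycleCosts:
        """Base-case per-cycle chronic-state cost components for a strategy."""
        block = self.costs.strategies[strategy]
        if include_indirect is None:
            include_indirect = self.costs.include_indirect
        return CycleCosts(
            direct_medical=visit_schedule_cost(self.visit_schedule(strategy)),
            direct_nonmedical=block.direct_nonmedical,
            indirect_nonmedical=self.costs.indirect_nonmedical_per_cycle,
            include_indirect=include_indirect,
        )


def load_config(path) -> AnalysisConfig:
    """Load and validate a YAML configuration file."""
    with open(path, "r", encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    try:
        return AnalysisConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc


def default_config() -> AnalysisConfig:
    """The shipped base-case configuration."""
    text = resources.files("lbpcea.data").joinpath("default_config.yaml").read_text("utf-8")
    return AnalysisConfig.model_validate(yaml.safe_load(text))


def dump_config(config: AnalysisConfig) -> str:
    """Serialize a configuration back to YAML (round-trips through load)."""
    return yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False)


def config_sha256(config: AnalysisConfig) -> str:
    """Stable content hash of a configuration, for run manifests."""
    canonical = yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()
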