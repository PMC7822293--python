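"""Parameter model: schema, validation, serialization and the transition catalog.

All user-modifiable inputs live in a single :class:`ParameterSet` grouped into
seven categories: demography, economics, baseline cooking, demand and
intervention, stove/fuel, health, and environment.  The JSON on-disk format is
one document with seven named sections; stove/fuel- and disease-indexed
quantities are named maps so every entry is auditable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .constants import (
    DEFAULT_HORIZON,
    DISEASES,
    IER_DISEASES,
    POLLUTANTS,
    TECHNOLOGIES,
    TRANSITION_GROUPS,
    TRANSITION_TABLE,
)
from .demand import DemandCurve, FuelDemandCurve


class Demography(BaseModel):
    total_population: float = Field(gt=0, description="persons")
    household_size: float = Field(gt=0, description="persons per household")
    children_u5_per_household: float = Field(gt=0, description="persons per household")

    @model_validator(mode="after")
    def _children_fit(self) -> "Demography":
        if self.children_u5_per_household >= self.household_size:
            raise ValueError(
                "children_u5_per_household must be below household_size"
            )
        return self

    @property
    def households(self) -> float:
        return self.total_population / self.household_size

    @property
    def adults_per_household(self) -> float:
        return self.household_size - self.children_u5_per_household


class EconomicParams(BaseModel):
    social_discount_rate: float = Field(ge=0, lt=1, description="fraction per year")
    shadow_time_fraction: float = Field(ge=0, le=1, description="fraction of wage")
    unskilled_wage: float = Field(ge=0, description="US$ per hour")
    value_per_daly: float = Field(ge=0, description="US$ per DALY")
    vsl: float = Field(ge=0, description="US$ per statistical death")
    coi_public_per_case: dict[str, float] = Field(description="US$ per case, by disease")
    coi_private_per_case: dict[str, float] = Field(description="US$ per case, by disease")

    @model_validator(mode="after")
    def _disease_maps(self) -> "EconomicParams":
        for name in ("coi_public_per_case", "coi_private_per_case"):
            m = getattr(self, name)
            if set(m) != set(DISEASES):
                raise ValueError(f"{name} must cover exactly the diseases {DISEASES}")
            if any(v < 0 for v in m.values()):
                raise ValueError(f"{name} values must be nonnegative")
        return self


class BaselineCooking(BaseModel):
    fraction_using: dict[str, float] = Field(
        description="fraction of households on each technology"
    )
    cook_hours_per_day: float = Field(ge=0)
    fuel_mass_per_year: float = Field(ge=0, description="kg per household")
    collection_hours_per_week: float = Field(ge=0)

    @model_validator(mode="after")
    def _fractions(self) -> "BaselineCooking":
        unknown = set(self.fraction_using) - set(TECHNOLOGIES)
        if unknown:
            raise ValueError(f"fraction_using has unknown technologies: {sorted(unknown)}")
        if any(not 0 <= f <= 1 for f in self.fraction_using.values()):
            raise ValueError("fraction_using values must lie in [0, 1]")
        if sum(self.fraction_using.values()) > 1 + 1e-9:
            raise ValueError("fraction_using must sum to at most 1")
        return self


class StoveFuelParams(BaseModel):
    """Per-technology stove and fuel characteristics.

    Emission factors are grams of pollutant per kg of fuel burned (per kWh for
    electric cooking, whose direct household emissions are zero).  ``fuel_is_biomass``
    drives the non-renewable-biomass adjustment of CO2 and the ecosystem
    benefit; fossil fuels count their CO2 in full.
    """

    stove_price: float = Field(ge=0, description="US$")
    fuel_price: float = Field(ge=0, description="US$ per kg (or unit)")
    annual_fuel_use: float = Field(ge=0, description="kg (or units) per household-year")
    stove_lifespan: float = Field(ge=1, description="years")
    efficiency: float = Field(gt=0, le=1, description="thermal efficiency fraction")
    emission_factor: dict[str, float] = Field(description="g per kg fuel, by pollutant")
    kitchen_pm25: float = Field(ge=0, description="µg/m³ kitchen-area concentration")
    learning_hours: float = Field(ge=0, description="one-time hours to learn use")
    maintenance_cost: float = Field(ge=0, description="US$ per year")
    cook_hours_per_day: float = Field(ge=0)
    collection_hours_per_week: float = Field(ge=0)
    fuel_is_biomass: bool = False

    @model_validator(mode="after")
    def _pollutants(self) -> "StoveFuelParams":
        if set(self.emission_factor) != set(POLLUTANTS):
            raise ValueError(
                f"emission_factor must cover exactly the pollutants {POLLUTANTS}"
            )
        if any(v < 0 for v in self.emission_factor.values()):
            # OC's cooling effect enters through a negative warming potential,
            # never through a negative emitted mass.
            raise ValueError("emission factors must be nonnegative")
        return self


class IERParams(BaseModel):
    """Integrated exposure-response parameters for one disease.

    Relative risk at personal PM2.5 concentration z is
    ``1 + alpha * (1 - exp(-gamma * (z - z_cf) ** delta))`` above the
    counterfactual concentration ``z_cf`` and 1 at or below it.
    """

    alpha: float = Field(ge=0)
    gamma: float = Field(gt=0)
    delta: float = Field(gt=0)
    z_cf: float = Field(ge=0, description="µg/m³ counterfactual")


class HealthParams(BaseModel):
    incidence: dict[str, float] = Field(description="cases/person/year, by disease")
    mortality: dict[str, float] = Field(description="deaths/person/year, by disease")
    life_expectancy_remaining: dict[str, float] = Field(description="years, by disease")
    daly_weight: dict[str, float] = Field(description="disability weight in [0,1]")
    morbidity_duration: dict[str, float] = Field(description="years, by disease")
    ier: dict[str, IERParams] = Field(
        description="exposure-response parameters; stroke is excluded by design"
    )
    exposure_adjustment: float = Field(gt=0, le=1)
    usage_rate: float = Field(ge=0, le=1)
    spillover_multiplier: float = Field(ge=1)
    lag_schedule: list[float] = Field(
        description="per-year fraction of steady-state health impact realised"
    )

    @model_validator(mode="after")
    def _check(self) -> "HealthParams":
        for name in (
            "incidence",
            "mortality",
            "life_expectancy_remaining",
            "daly_weight",
            "morbidity_duration",
        ):
            m = getattr(self, name)
            if set(m) != set(DISEASES):
                raise ValueError(f"{name} must cover exactly the diseases {DISEASES}")
            if any(v < 0 for v in m.values()):
                raise ValueError(f"{name} values must be nonnegative")
        if any(not 0 <= w <= 1 for w in self.daly_weight.values()):
            raise ValueError("daly_weight values must lie in [0, 1]")
        # stroke rides on the least-reduced of the other four conditions and
        # must not carry its own exposure-response curve
        if set(self.ier) != set(IER_DISEASES):
            raise ValueError(
                f"ier must cover exactly {IER_DISEASES} (stroke has no curve)"
            )
        lag = self.lag_schedule
        if not lag:
            raise ValueError("lag_schedule must be nonempty")
        if any(not 0 <= v <= 1 for v in lag):
            raise ValueError("lag_schedule values must lie in [0, 1]")
        if any(b < a for a, b in zip(lag, lag[1:])):
            raise ValueError("lag_schedule must be nondecreasing")
        if abs(lag[-1] - 1.0) > 1e-12:
            raise ValueError("lag_schedule must reach 1")
        return self


class EnvironmentParams(BaseModel):
    tree_replacement_cost: float = Field(ge=0, description="US$ per kg biomass")
    scc: float = Field(ge=0, description="US$ per t CO2e (social cost of carbon)")
    gwp: dict[str, float] = Field(description="t CO2e per t, by pollutant")
    fnrb: float = Field(ge=0, le=1, description="fraction of non-renewable biomass")
    basket: Literal["basic", "full"] = "full"

    @model_validator(mode="after")
    def _gwp(self) -> "EnvironmentParams":
        if set(self.gwp) != set(POLLUTANTS):
            raise ValueError(f"gwp must cover exactly the pollutants {POLLUTANTS}")
        if self.gwp["oc"] > 0:
            raise ValueError("gwp['oc'] must be <= 0 (organic carbon is net cooling)")
        if self.gwp["co2"] != 1:
            raise ValueError("gwp['co2'] must equal 1 by definition")
        return self


class ProgramUnitCosts(BaseModel):
    """Fixed annual program implementation costs plus a per-adopter
    promotion cost (the only program cost that scales with users targeted)."""

    personnel: float = Field(ge=0, description="US$/year")
    training: float = Field(ge=0, description="US$/year")
    advertising: float = Field(ge=0, description="US$/year")
    equipment: float = Field(ge=0, description="US$/year")
    promotion_per_adopter: float = Field(ge=0, default=0.0, description="US$/adopter")

    @property
    def fixed_annual(self) -> float:
        return self.personnel + self.training + self.advertising + self.equipment


class InterventionParams(BaseModel):
    subsidy_stove: float = Field(ge=0, le=1, description="fraction of stove price")
    subsidy_fuel: float = Field(ge=0, le=1, description="fraction of recurrent fuel cost")
    leakage: float = Field(ge=0, description="fraction of subsidy outlay lost in transit")
    financing_boost: float = Field(ge=0, default=0.40, description="WTP pivot fraction")
    bcc_boost: float = Field(ge=0, default=0.10, description="WTP pivot fraction")
    fuel_elasticity: float = Field(lt=0, default=-1.0)
    program_unit_costs: ProgramUnitCosts
    ramp: Literal["default", "immediate"] = "default"
    stove_demand: dict[str, DemandCurve] = Field(
        description="stove demand curve per target technology"
    )
    fuel_demand: dict[str, FuelDemandCurve] = Field(
        default_factory=dict, description="recurrent-cost demand per fuel (for bans)"
    )

    @model_validator(mode="after")
    def _techs(self) -> "InterventionParams":
        for name in ("stove_demand", "fuel_demand"):
            unknown = set(getattr(self, name)) - set(TECHNOLOGIES)
            if unknown:
                raise ValueError(f"{name} has unknown technologies: {sorted(unknown)}")
        return self


class TransitionSpec(BaseModel):
    id: int = Field(ge=1, le=16)
    from_tech: str
    to_tech: str
    group: str

    @model_validator(mode="after")
    def _check(self) -> "TransitionSpec":
        if self.from_tech == self.to_tech:
            raise ValueError("from_tech and to_tech must differ")
        for t in (self.from_tech, self.to_tech):
            if t not in TECHNOLOGIES:
                raise ValueError(f"unknown technology {t!r}")
        if self.group not in TRANSITION_GROUPS:
            raise ValueError(f"unknown transition group {self.group!r}")
        return self


class PolicySpec(BaseModel):
    """One policy instrument (with optional stove-subsidy stacking).

    Exactly one of fuel subsidy, financing, or behaviour-change communication
    may be selected per transition; each may be combined with a stove subsidy.
    A ban stands alone.
    """

    instrument: Literal["stove_subsidy", "fuel_subsidy", "financing", "bcc", "ban"]
    with_stove_subsidy: bool = False

    @model_validator(mode="after")
    def _combination(self) -> "PolicySpec":
        if self.instrument == "ban" and self.with_stove_subsidy:
            raise ValueError("a ban cannot be combined with a stove subsidy")
        if self.instrument == "stove_subsidy" and self.with_stove_subsidy:
            raise ValueError(
                "instrument 'stove_subsidy' already is the stove subsidy; "
                "use with_stove_subsidy only with fuel_subsidy/financing/bcc"
            )
        return self


class ParameterSet(BaseModel):
    """All user-modifiable model inputs, grouped in seven categories."""

    demography: Demography
    economics: EconomicParams
    baseline_cooking: BaselineCooking
    interventions: InterventionParams
    stove_fuel: dict[str, StoveFuelParams]
    health: HealthParams
    environment: EnvironmentParams
    horizon_years: int = Field(ge=1, default=DEFAULT_HORIZON)

    @model_validator(mode="after")
    def _cross_checks(self) -> "ParameterSet":
        unknown = set(self.stove_fuel) - set(TECHNOLOGIES)
        if unknown:
            raise ValueError(f"stove_fuel has unknown technologies: {sorted(unknown)}")
        missing = set(self.baseline_cooking.fraction_using) - set(self.stove_fuel)
        if missing:
            raise ValueError(
                f"baseline technologies lack stove_fuel parameters: {sorted(missing)}"
            )
        return self


def transition_catalog() -> list[TransitionSpec]:
    """The sixteen supported fuel/technology transitions, in four groups."""
    return [
        TransitionSpec(id=i, from_tech=f, to_tech=t, group=g)
        for (i, f, t, g) in TRANSITION_TABLE
    ]


def get_transition(transition_id: int) -> TransitionSpec:
    for spec in transition_catalog():
        if spec.id == transition_id:
            return spec
    raise KeyError(f"no transition with id {transition_id}")


def load_parameters(path: str | Path) -> ParameterSet:
    """Read and fully validate a JSON parameter file."""
    text = Path(path).read_text()
    return ParameterSet.model_validate_json(text)


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a parameter set as a pretty-printed JSON document."""
    Path(path).write_text(params.model_dump_json(indent=2) + "\n")


def flatten_parameters(params: ParameterSet) -> pd.DataFrame:
    """Flatten the parameter set to a (section, parameter, value) table for
    review/CSV export."""
    rows: list[tuple[str, str, object]] = []

    def walk(section: str, prefix: str, obj: object) -> None:
        if isinstance(obj, dict):
            for k, v in obj.items():
                walk(section, f"{prefix}.{k}" if prefix else str(k), v)
        elif isinstance(obj, list):
            for i, v in enumerate(obj):
                walk(section, f"{prefix}[{i}]", v)
        else:
            rows.append((section, prefix, obj))

    dumped = params.model_dump()
    for section, content in dumped.items():
        walk(section, "", content)
    return pd.DataFrame(rows, columns=["section", "parameter", "value"])


def export_parameters_csv(params: ParameterSet, path: str | Path) -> None:
    flatten_parameters(params).to_csv(path, index=False)


def parameters_digest(params: ParameterSet) -> str:
    """Stable content hash of a parameter set, for report provenance."""
    import hashlib

    canonical = json.dumps(params.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
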