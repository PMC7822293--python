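"""Scenario orchestration: transitions × policy × subsidy sweeps, laddering,
and report writing.

A scenario names one or more transitions (with laddering shares splitting a
baseline user population across them), a single policy package, and a grid
of stove-subsidy levels.  Each (transition, subsidy) cell runs the full
pipeline — demand response, health impact, environmental impact, cost and
benefit streams — and yields an outcome row; laddered components are
combined into a population-weighted total row.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .aggregate import (
    ScenarioOutcome,
    YearlyStream,
    assemble_outcome,
    breakeven_subsidy,
    coverage_by_year,
    government_cost_stream,
    new_adopters_by_year,
    npv,
    private_cost_stream,
    ramp_schedule,
    stove_purchases_by_year,
    time_savings_stream,
)
from .constants import FUEL_SUBSIDY_ELIGIBLE
from .demand import (
    apply_wtp_pivot,
    ban_outcome,
    fuel_subsidized_uptake,
    stove_subsidy_uptake,
)
from .environment import yearly_environment_benefit
from .health import personal_exposure, stacked_exposure, yearly_health_benefit
from .params import ParameterSet, PolicySpec, TransitionSpec, get_transition, parameters_digest

logger = logging.getLogger("cleancook")

COMBINED_ID = 0  # sentinel transition id for the laddered total row


class ScenarioValidationError(ValueError):
    """A scenario violates a structural rule (policy combination, shares)."""


class LadderComponent(BaseModel):
    transition_id: int = Field(ge=1, le=16)
    share: float = Field(gt=0, le=1)


class Scenario(BaseModel):
    """A runnable scenario: laddered transitions, one policy, a subsidy grid."""

    transitions: list[LadderComponent]
    policy: PolicySpec
    subsidy_grid: list[float] = Field(default=[0.0, 0.25, 0.5, 0.75, 1.0])
    cer_basis: Literal["gross", "net"] = "gross"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "Scenario":
        if not self.transitions:
            raise ValueError("scenario needs at least one transition")
        ids = [c.transition_id for c in self.transitions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate transition ids in ladder")
        if not self.subsidy_grid:
            raise ValueError("subsidy_grid must be nonempty")
        if any(not 0 <= s <= 1 for s in self.subsidy_grid):
            raise ValueError("subsidy_grid values must lie in [0, 1]")
        # laddering shares over transitions leaving the same baseline
        # technology must exhaust that population
        by_from: dict[str, float] = {}
        for comp in self.transitions:
            spec = get_transition(comp.transition_id)
            by_from[spec.from_tech] = by_from.get(spec.from_tech, 0.0) + comp.share
        for tech, total in by_from.items():
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"laddering shares for baseline {tech!r} sum to {total}, not 1"
                )
        return self


def validate_policy_for_transition(policy: PolicySpec, transition: TransitionSpec) -> None:
    """Enforce instrument applicability for a given transition."""
    if policy.instrument == "fuel_subsidy" and transition.to_tech not in FUEL_SUBSIDY_ELIGIBLE:
        raise ScenarioValidationError(
            f"fuel subsidy is only available for targets "
            f"{sorted(FUEL_SUBSIDY_ELIGIBLE)}; transition {transition.id} "
            f"targets {transition.to_tech!r}"
        )


def _lag_weights(lag_schedule: list[float], horizon: int) -> np.ndarray:
    lag = np.asarray(lag_schedule, dtype=float)
    if len(lag) >= horizon:
        return lag[:horizon]
    return np.concatenate([lag, np.full(horizon - len(lag), lag[-1])])


def run_single(
    params: ParameterSet,
    transition: TransitionSpec,
    policy: PolicySpec,
    stove_subsidy: float,
    share: float = 1.0,
    cer_basis: Literal["gross", "net"] = "gross",
) -> ScenarioOutcome:
    """Run the full pipeline for one transition under one policy at one
    stove-subsidy level, targeting ``share`` of the baseline users."""
    validate_policy_for_transition(policy, transition)
    iv = params.interventions
    econ = params.economics
    hp = params.health
    env = params.environment
    demo = params.demography
    from_sf = params.stove_fuel[transition.from_tech]
    to_sf = params.stove_fuel[transition.to_tech]
    horizon = params.horizon_years
    r = econ.social_discount_rate

    try:
        curve = iv.stove_demand[transition.to_tech]
    except KeyError:
        raise ScenarioValidationError(
            f"no stove demand curve for target technology {transition.to_tech!r}"
        ) from None

    # --- demand response -------------------------------------------------
    instrument = policy.instrument
    s_stove = stove_subsidy if (instrument == "stove_subsidy" or policy.with_stove_subsidy) else 0.0
    s_fuel = iv.subsidy_fuel if instrument == "fuel_subsidy" else 0.0
    if instrument == "financing":
        curve = apply_wtp_pivot(curve, iv.financing_boost)
    elif instrument == "bcc":
        curve = apply_wtp_pivot(curve, iv.bcc_boost)

    cs_loss_per_hh = 0.0
    if instrument == "ban":
        fuel_curve = iv.fuel_demand.get(transition.from_tech)
        if fuel_curve is None:
            raise ScenarioValidationError(
                f"a ban on {transition.from_tech!r} needs a fuel demand curve"
            )
        banned_annual_cost = from_sf.fuel_price * from_sf.annual_fuel_use
        substitute_annual_cost = to_sf.fuel_price * to_sf.annual_fuel_use
        _, cs_loss_per_hh = ban_outcome(
            fuel_curve,
            banned_annual_cost,
            substitute_annual_cost,
            substitute_curve=iv.fuel_demand.get(transition.to_tech),
        )
        uptake = curve.c_max  # coverage forced to the target's maximum
    else:
        uptake = stove_subsidy_uptake(curve, to_sf.stove_price, s_stove)
        if s_fuel > 0:
            uptake = fuel_subsidized_uptake(
                uptake, curve.c_max, 1.0 - s_fuel, iv.fuel_elasticity
            )

    # --- roll-out ---------------------------------------------------------
    households = demo.households
    n_target = share * params.baseline_cooking.fraction_using.get(transition.from_tech, 0.0) * households
    target_population = n_target * demo.household_size
    adopters = uptake * n_target
    ramp = ramp_schedule(iv.ramp, horizon)
    covered = coverage_by_year(adopters, ramp)
    new_adopters = new_adopters_by_year(covered)
    purchases = stove_purchases_by_year(new_adopters, to_sf.stove_lifespan)
    lag = _lag_weights(hp.lag_schedule, horizon)

    # --- exposure ---------------------------------------------------------
    z_pre = personal_exposure(from_sf.kitchen_pm25, hp.exposure_adjustment)
    z_post = personal_exposure(
        stacked_exposure(from_sf.kitchen_pm25, to_sf.kitchen_pm25, hp.usage_rate),
        hp.exposure_adjustment,
    )

    # --- per-year health and environment ---------------------------------
    health_money = np.zeros(horizon)
    coi_public = np.zeros(horizon)
    dalys = np.zeros(horizon)
    climate = np.zeros(horizon)
    ecosystem = np.zeros(horizon)
    for t in range(horizon):
        hb = yearly_health_benefit(
            covered[t],
            demo.children_u5_per_household,
            demo.adults_per_household,
            z_pre,
            z_post,
            hp,
            econ,
            r,
            lag[t],
            social=True,
        )
        health_money[t] = hb.total_money
        coi_public[t] = hb.coi_savings_public
        dalys[t] = hb.dalys
        climate[t], ecosystem[t], _ = yearly_environment_benefit(
            from_sf, to_sf, covered[t], hp.usage_rate, env
        )

    # --- money streams ----------------------------------------------------
    fuel_outlay = None
    if s_fuel > 0:
        # the fuel subsidy flows to every user of the target fuel, including
        # households that already used it before the program
        existing_users = (
            params.baseline_cooking.fraction_using.get(transition.to_tech, 0.0) * households * share
        )
        fuel_cost = to_sf.fuel_price * to_sf.annual_fuel_use
        fuel_outlay = s_fuel * fuel_cost * (existing_users + covered * hp.usage_rate)

    gov = government_cost_stream(
        horizon,
        iv.program_unit_costs,
        new_adopters,
        purchases,
        to_sf.stove_price,
        s_stove,
        iv.leakage,
        fuel_subsidy_outlay=fuel_outlay,
    )
    coi_stream = YearlyStream(coi_public, "public COI savings", "government")

    # social resource costs: subsidies and leakage are transfers, so stove,
    # fuel and program costs enter once at their full (pre-subsidy) value
    resource_private = private_cost_stream(
        horizon, covered, new_adopters, purchases, from_sf, to_sf,
        stove_subsidy=0.0, fuel_subsidy=0.0, usage_rate=hp.usage_rate, econ=econ,
    )
    resource_private.label = "household resource costs"
    resource_private.perspective = "social"
    program_resources = YearlyStream(
        np.full(horizon, iv.program_unit_costs.fixed_annual)
        + iv.program_unit_costs.promotion_per_adopter * new_adopters,
        "program resource costs",
        "social",
    )
    social_costs: list[YearlyStream] = [program_resources, resource_private]
    if cs_loss_per_hh > 0:
        social_costs.append(
            YearlyStream(covered * cs_loss_per_hh, "consumer surplus loss", "social")
        )

    social_benefits = [
        YearlyStream(health_money, "health benefits", "social"),
        time_savings_stream(horizon, covered, from_sf, to_sf, hp.usage_rate, econ),
        YearlyStream(climate, "climate benefits", "social"),
        YearlyStream(ecosystem, "ecosystem benefits", "social"),
    ]

    outcome = assemble_outcome(
        transition_id=transition.id,
        policy=_policy_label(policy),
        stove_subsidy=stove_subsidy,
        target_coverage=uptake,
        target_households=n_target,
        target_population=target_population,
        gov_stream=gov,
        public_coi_stream=coi_stream,
        social_benefit_streams=social_benefits,
        social_cost_streams=social_costs,
        dalys_stream=dalys,
        discount_rate=r,
        cer_basis=cer_basis,
    )
    logger.info(
        "run_single transition=%d policy=%s subsidy=%.2f coverage=%.3f "
        "npv=%.1f dalys=%.1f",
        transition.id, outcome.policy, stove_subsidy, uptake,
        outcome.pv_social_net_benefits, outcome.dalys_avoided,
    )
    return outcome


def _policy_label(policy: PolicySpec) -> str:
    label = policy.instrument
    if policy.with_stove_subsidy and policy.instrument != "stove_subsidy":
        label += "+stove_subsidy"
    return label


def combine_outcomes(
    components: list[ScenarioOutcome],
    stove_subsidy: float,
    cer_basis: Literal["gross", "net"] = "gross",
) -> ScenarioOutcome:
    """Population-weighted laddered total: money metrics and DALYs sum;
    coverage averages over the union target population; per-capita cost uses
    the union population."""
    from .aggregate import cer as cer_fn

    pop = sum(c.target_population for c in components)
    hh = sum(c.target_households for c in components)
    pv_net = sum(c.pv_net_public_cost for c in components)
    pv_coi = sum(c.pv_public_coi_savings for c in components)
    pv_gross = sum(c.pv_breakdown["pv_government_cost_gross"] for c in components)
    dalys = sum(c.dalys_avoided for c in components)
    coverage = (
        sum(c.target_coverage * c.target_population for c in components) / pop
        if pop > 0
        else 0.0
    )
    return ScenarioOutcome(
        transition_id=COMBINED_ID,
        policy=components[0].policy,
        stove_subsidy=stove_subsidy,
        target_coverage=coverage,
        target_households=hh,
        target_population=pop,
        pv_net_public_cost=pv_net,
        per_capita_public_cost=pv_net / pop if pop > 0 else 0.0,
        pv_public_coi_savings=pv_coi,
        dalys_avoided=dalys,
        cer=cer_fn(pv_gross, pv_coi, dalys, basis=cer_basis),
        pv_social_net_benefits=sum(c.pv_social_net_benefits for c in components),
        pv_breakdown={"pv_government_cost_gross": pv_gross},
    )


def run_scenario(scenario: Scenario, params: ParameterSet) -> list[ScenarioOutcome]:
    """Run every (subsidy level × laddered component) cell plus, when the
    ladder has several components, a combined total row per subsidy level."""
    specs = [(get_transition(c.transition_id), c.share) for c in scenario.transitions]
    for spec, _ in specs:
        validate_policy_for_transition(scenario.policy, spec)
    outcomes: list[ScenarioOutcome] = []
    for subsidy in scenario.subsidy_grid:
        components = [
            run_single(params, spec, scenario.policy, subsidy, share=share,
                       cer_basis=scenario.cer_basis)
            for spec, share in specs
        ]
        outcomes.extend(components)
        if len(components) > 1:
            outcomes.append(
                combine_outcomes(components, subsidy, cer_basis=scenario.cer_basis)
            )
    return outcomes


def subsidy_sweep(
    scenario: Scenario, params: ParameterSet, grid: list[float] | None = None
) -> pd.DataFrame:
    """Outcome table over a subsidy grid: one column per subsidy level, the
    outcome metrics as rows (per transition).  Emits a warning if coverage
    is not monotone in subsidy."""
    sweep = scenario.model_copy(
        update={"subsidy_grid": sorted(grid if grid is not None else scenario.subsidy_grid)}
    )
    outcomes = run_scenario(sweep, params)
    df = pd.DataFrame([o.as_row() for o in outcomes])
    for tid, grp in df.groupby("transition_id"):
        cov = grp.sort_values("stove_subsidy")["target_coverage"].to_numpy()
        if np.any(np.diff(cov) < -1e-12):
            warnings.warn(
                f"coverage not monotone in subsidy for transition {tid}",
                stacklevel=2,
            )
    return df


def sweep_table(df: pd.DataFrame, transition_id: int | None = None) -> pd.DataFrame:
    """Pivot a sweep frame to the report layout: metrics as rows, one column
    per subsidy level."""
    if transition_id is not None:
        df = df[df["transition_id"] == transition_id]
    metrics = [
        "target_coverage",
        "pv_net_public_cost",
        "per_capita_public_cost",
        "pv_public_coi_savings",
        "dalys_avoided",
        "cer",
        "pv_social_net_benefits",
    ]
    wide = df.set_index("stove_subsidy")[metrics].T
    wide.columns = [f"{100 * s:g}%" for s in wide.columns]
    return wide


def social_npv_of_subsidy(
    params: ParameterSet,
    transition: TransitionSpec,
    policy: PolicySpec,
    cer_basis: Literal["gross", "net"] = "gross",
):
    """Social NPV as a function of the stove-subsidy level (for breakeven
    searches)."""

    def f(s: float) -> float:
        return run_single(params, transition, policy, s, cer_basis=cer_basis).pv_social_net_benefits

    return f


def find_breakeven_subsidy(
    params: ParameterSet, transition: TransitionSpec, policy: PolicySpec
) -> float | None:
    """Stove-subsidy level at which social NPV crosses zero, if any."""
    return breakeven_subsidy(social_npv_of_subsidy(params, transition, policy))


def write_report(
    outcomes: list[ScenarioOutcome],
    out_dir: str | Path,
    fmt: Literal["csv", "json"] = "csv",
    params: ParameterSet | None = None,
    seed: int | None = None,
) -> list[Path]:
    """Write an outcome report with a provenance block (parameter digest,
    seed, tool version).  Bit-stable for fixed inputs."""
    if not outcomes:
        raise ValueError("no outcomes to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {
        "tool_version": __version__,
        "parameters_digest": parameters_digest(params) if params is not None else None,
        "seed": seed,
    }
    rows = [o.as_row() for o in outcomes]
    written: list[Path] = []
    if fmt == "csv":
        path = out / "outcomes.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        written.append(path)
        ppath = out / "provenance.json"
        ppath.write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
        written.append(ppath)
    elif fmt == "json":
        path = out / "outcomes.json"
        path.write_text(
            json.dumps({"provenance": provenance, "outcomes": rows}, indent=2, sort_keys=True)
            + "\n"
        )
        written.append(path)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    logger.info("write_report fmt=%s files=%s", fmt, [str(p) for p in written])
    return written
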