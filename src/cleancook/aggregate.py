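"""Yearly cost/benefit streams, discounting, and outcome metrics.

Everything is aggregated over a fixed policy horizon (15 years by default)
as per-year money or quantity vectors.  Discounting is end-of-year with the
first year undiscounted: ``PV = sum_t v[t] / (1+r)**(t-1)``.  The default
roll-out ramp spends two planning years without benefits, then phases in a
third of the target population per year for three years; the alternative
treats the policy as fully implemented from year one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .constants import DEFAULT_HORIZON
from .params import EconomicParams, ProgramUnitCosts, StoveFuelParams

Perspective = Literal["government", "private", "social"]


@dataclass
class YearlyStream:
    """A per-year vector of money (US$) or quantities over the horizon."""

    values: np.ndarray
    label: str
    perspective: Perspective

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("stream must be one-dimensional")

    def __len__(self) -> int:
        return len(self.values)


def ramp_schedule(mode: str, horizon: int = DEFAULT_HORIZON) -> np.ndarray:
    """Per-year coverage weights for the roll-out.

    ``default``: [0, 0, 1/3, 2/3, 1, 1, ...] — two planning years, then a
    third of the target population added each year for three years.
    ``immediate``: all ones.
    """
    if mode == "immediate":
        return np.ones(horizon)
    if mode == "default":
        if horizon < 5:
            raise ValueError("default ramp needs a horizon of at least 5 years")
        w = np.ones(horizon)
        w[:4] = [0.0, 0.0, 1.0 / 3.0, 2.0 / 3.0]
        return w
    raise ValueError(f"unknown ramp mode {mode!r}")


def coverage_by_year(target_adopters: float, ramp: np.ndarray) -> np.ndarray:
    """Covered (adopting) households per year under the ramp."""
    return target_adopters * ramp


def new_adopters_by_year(covered: np.ndarray) -> np.ndarray:
    """Households newly adopting each year (first differences, floored at 0)."""
    prev = np.concatenate([[0.0], covered[:-1]])
    return np.maximum(covered - prev, 0.0)


def stove_purchases_by_year(new_adopters: np.ndarray, lifespan: float) -> np.ndarray:
    """Stove purchases per year: first purchase at adoption, replacement every
    ``lifespan`` years thereafter within the horizon."""
    horizon = len(new_adopters)
    step = max(1, int(round(lifespan)))
    purchases = np.zeros(horizon)
    for tau in range(horizon):
        if new_adopters[tau] <= 0:
            continue
        for t in range(tau, horizon, step):
            purchases[t] += new_adopters[tau]
    return purchases


def npv(stream: YearlyStream | Sequence[float] | np.ndarray, rate: float) -> float:
    """Present value: end-of-year discounting, year 1 undiscounted."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    values = stream.values if isinstance(stream, YearlyStream) else np.asarray(stream, float)
    t = np.arange(len(values))
    return float(np.sum(values / (1.0 + rate) ** t))


def government_cost_stream(
    horizon: int,
    program: ProgramUnitCosts,
    new_adopters: np.ndarray,
    stove_purchases: np.ndarray,
    stove_price: float,
    stove_subsidy: float,
    leakage: float,
    fuel_subsidy_outlay: np.ndarray | None = None,
) -> YearlyStream:
    """Government outlays: fixed program costs, per-adopter promotion, stove
    subsidy at purchase/replacement years, and recurrent fuel subsidy — the
    subsidy flows inflated by (1 + leakage)."""
    values = np.full(horizon, program.fixed_annual, dtype=float)
    values += program.promotion_per_adopter * new_adopters
    values += stove_subsidy * stove_price * stove_purchases * (1.0 + leakage)
    if fuel_subsidy_outlay is not None:
        values += np.asarray(fuel_subsidy_outlay, float) * (1.0 + leakage)
    return YearlyStream(values, "government costs", "government")


def private_cost_stream(
    horizon: int,
    covered: np.ndarray,
    new_adopters: np.ndarray,
    stove_purchases: np.ndarray,
    from_sf: StoveFuelParams,
    to_sf: StoveFuelParams,
    stove_subsidy: float,
    fuel_subsidy: float,
    usage_rate: float,
    econ: EconomicParams,
) -> YearlyStream:
    """Adopting households' costs: their stove share, one-time learning time,
    net maintenance, and the net recurrent fuel bill change (post-subsidy
    prices, scaled by the usage rate).  Collection-time changes are valued in
    the time-savings benefit stream, not here."""
    values = np.zeros(horizon)
    values += (1.0 - stove_subsidy) * to_sf.stove_price * stove_purchases
    shadow_wage = econ.shadow_time_fraction * econ.unskilled_wage
    values += new_adopters * to_sf.learning_hours * shadow_wage
    values += covered * (to_sf.maintenance_cost - from_sf.maintenance_cost)
    new_fuel = (1.0 - fuel_subsidy) * to_sf.fuel_price * to_sf.annual_fuel_use
    old_fuel = from_sf.fuel_price * from_sf.annual_fuel_use
    values += covered * usage_rate * (new_fuel - old_fuel)
    return YearlyStream(values, "private costs", "private")


def time_savings_stream(
    horizon: int,
    covered: np.ndarray,
    from_sf: StoveFuelParams,
    to_sf: StoveFuelParams,
    usage_rate: float,
    econ: EconomicParams,
) -> YearlyStream:
    """Value of cooking and fuel-collection time saved, at the shadow value
    of time (a fraction of the unskilled wage)."""
    hours_per_year = (
        (from_sf.cook_hours_per_day - to_sf.cook_hours_per_day) * 365.0
        + (from_sf.collection_hours_per_week - to_sf.collection_hours_per_week) * 52.0
    )
    shadow_wage = econ.shadow_time_fraction * econ.unskilled_wage
    values = covered * usage_rate * hours_per_year * shadow_wage
    return YearlyStream(np.asarray(values, float), "time savings", "social")


def cer(
    pv_public_cost: float,
    pv_coi_savings: float,
    dalys: float,
    basis: Literal["gross", "net"] = "gross",
) -> float | None:
    """Cost-effectiveness ratio in US$/DALY avoided; ``None`` ("n.a.") when
    no DALYs are avoided.  Gross uses public cost as-is; net subtracts public
    cost-of-illness savings."""
    if dalys < 0:
        raise ValueError("dalys must be nonnegative")
    if dalys == 0:
        return None
    numerator = pv_public_cost if basis == "gross" else pv_public_cost - pv_coi_savings
    return numerator / dalys


@dataclass
class ScenarioOutcome:
    """The outcome row for one transition/policy/subsidy combination."""

    transition_id: int
    policy: str
    stove_subsidy: float
    target_coverage: float
    target_households: float
    target_population: float
    pv_net_public_cost: float
    per_capita_public_cost: float
    pv_public_coi_savings: float
    dalys_avoided: float
    cer: float | None
    pv_social_net_benefits: float
    pv_breakdown: dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict[str, object]:
        return {
            "transition_id": self.transition_id,
            "policy": self.policy,
            "stove_subsidy": self.stove_subsidy,
            "target_coverage": self.target_coverage,
            "pv_net_public_cost": self.pv_net_public_cost,
            "per_capita_public_cost": self.per_capita_public_cost,
            "pv_public_coi_savings": self.pv_public_coi_savings,
            "dalys_avoided": self.dalys_avoided,
            "cer": "n.a." if self.cer is None else self.cer,
            "pv_social_net_benefits": self.pv_social_net_benefits,
        }


def assemble_outcome(
    *,
    transition_id: int,
    policy: str,
    stove_subsidy: float,
    target_coverage: float,
    target_households: float,
    target_population: float,
    gov_stream: YearlyStream,
    public_coi_stream: YearlyStream,
    social_benefit_streams: Sequence[YearlyStream],
    social_cost_streams: Sequence[YearlyStream],
    dalys_stream: np.ndarray,
    discount_rate: float,
    cer_basis: Literal["gross", "net"] = "gross",
) -> ScenarioOutcome:
    """Discount all streams and produce the outcome metrics.

    Government cost is reported net of public cost-of-illness savings; social
    net benefits treat subsidies (and their leakage) as transfers, so the
    caller passes resource-cost streams, each counted once.
    """
    horizon = len(gov_stream)
    for s in [public_coi_stream, *social_benefit_streams, *social_cost_streams]:
        if len(s) != horizon:
            raise ValueError(f"stream {s.label!r} horizon mismatch")
    r = discount_rate
    pv_gov = npv(gov_stream, r)
    pv_coi = npv(public_coi_stream, r)
    pv_benefits = {s.label: npv(s, r) for s in social_benefit_streams}
    pv_costs = {s.label: npv(s, r) for s in social_cost_streams}
    dalys = npv(dalys_stream, r)
    pv_net_public = pv_gov - pv_coi
    social_npv = sum(pv_benefits.values()) - sum(pv_costs.values())
    return ScenarioOutcome(
        transition_id=transition_id,
        policy=policy,
        stove_subsidy=stove_subsidy,
        target_coverage=target_coverage,
        target_households=target_households,
        target_population=target_population,
        pv_net_public_cost=pv_net_public,
        per_capita_public_cost=(
            pv_net_public / target_population if target_population > 0 else 0.0
        ),
        pv_public_coi_savings=pv_coi,
        dalys_avoided=dalys,
        cer=cer(pv_gov, pv_coi, dalys, basis=cer_basis),
        pv_social_net_benefits=social_npv,
        pv_breakdown={
            "pv_government_cost_gross": pv_gov,
            **{f"pv_benefit:{k}": v for k, v in pv_benefits.items()},
            **{f"pv_cost:{k}": v for k, v in pv_costs.items()},
        },
    )


def breakeven_subsidy(
    social_npv_at: Callable[[float], float],
    lo: float = 0.0,
    hi: float = 1.0,
    tol: float = 1e-6,
) -> float | None:
    """Bisection for the stove-subsidy level at which social NPV crosses zero.

    Returns ``None`` when no sign change exists on [lo, hi].  On fixtures
    where NPV is monotone in subsidy above the adoption threshold, the
    crossing is unique.
    """
    f_lo, f_hi = social_npv_at(lo), social_npv_at(hi)
    if f_lo == 0:
        return lo
    if f_hi == 0:
        return hi
    if f_lo * f_hi > 0:
        return None
    from scipy.optimize import brentq

    return float(brentq(social_npv_at, lo, hi, xtol=tol))
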