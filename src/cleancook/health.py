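"""Health impact: exposure change → relative risk → avoided burden → DALYs → money.

Personal PM2.5 exposure is the kitchen-area concentration scaled by an
exposure adjustment factor; partial displacement of the old stove (stacking)
is a usage-rate-weighted mixture of old and new concentrations.  Disease-
specific relative risks follow an integrated exposure-response curve of the
form ``1 + alpha * (1 - exp(-gamma * (z - z_cf)**delta))``; the potential
impact fraction of an exposure reduction converts prevented risk into avoided
cases and deaths.  Stroke, which has no curve of its own, is assigned the
least-reduced impact fraction among the other four conditions.  Years of life
lost are discounted continuously over remaining life expectancy; no age
weighting is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import CHILD_DISEASES, DISEASES, IER_DISEASES
from .params import EconomicParams, HealthParams, IERParams


def personal_exposure(kitchen_pm25: float, exposure_adjustment: float) -> float:
    """Personal PM2.5 exposure from a kitchen-area concentration."""
    if kitchen_pm25 < 0:
        raise ValueError("kitchen_pm25 must be nonnegative")
    if not 0 < exposure_adjustment <= 1:
        raise ValueError("exposure_adjustment must be in (0, 1]")
    return kitchen_pm25 * exposure_adjustment


def stacked_exposure(z_old: float, z_new: float, usage_rate: float) -> float:
    """Concentration under stove stacking: usage-weighted mixture."""
    if not 0 <= usage_rate <= 1:
        raise ValueError("usage_rate must be in [0, 1]")
    return usage_rate * z_new + (1 - usage_rate) * z_old


def relative_risk(z: float, ier: IERParams) -> float:
    """Relative risk at personal concentration ``z`` (µg/m³).

    1 at or below the counterfactual ``z_cf``; approaches ``1 + alpha``
    as z grows; continuous and nondecreasing.
    """
    if z < 0:
        raise ValueError("concentration must be nonnegative")
    if z <= ier.z_cf:
        return 1.0
    return 1.0 + ier.alpha * (1.0 - math.exp(-ier.gamma * (z - ier.z_cf) ** ier.delta))


def impact_fraction(rr_pre: float, rr_post: float) -> float:
    """Potential impact fraction of moving risk from ``rr_pre`` to ``rr_post``."""
    if not rr_pre >= rr_post >= 1:
        raise ValueError("require rr_pre >= rr_post >= 1")
    return (rr_pre - rr_post) / rr_pre


def stroke_reduction(reductions: dict[str, float]) -> float:
    """Stroke impact fraction: the minimum over the four modelled conditions."""
    missing = set(IER_DISEASES) - set(reductions)
    if missing:
        raise ValueError(f"missing reductions for {sorted(missing)}")
    vals = [reductions[d] for d in IER_DISEASES]
    if any(not 0 <= v <= 1 for v in vals):
        raise ValueError("reductions must lie in [0, 1]")
    return min(vals)


def disease_reductions(z_pre: float, z_post: float, hp: HealthParams) -> dict[str, float]:
    """Per-disease impact fractions for an exposure change, including the
    stroke rule."""
    out: dict[str, float] = {}
    for d in IER_DISEASES:
        rr_pre = relative_risk(z_pre, hp.ier[d])
        rr_post = relative_risk(z_post, hp.ier[d])
        out[d] = impact_fraction(rr_pre, rr_post)
    out["stroke"] = stroke_reduction(out)
    return out


def avoided_burden(
    exposed_persons: dict[str, float],
    hp: HealthParams,
    reductions: dict[str, float],
    lag_weight: float,
    social: bool = True,
) -> tuple[dict[str, float], dict[str, float]]:
    """Avoided (cases, deaths) per disease for one year.

    ``exposed_persons`` maps each disease to the covered at-risk population
    (children under five for ALRI, adults otherwise — the caller allocates).
    The social perspective multiplies by the ambient-air spillover factor;
    the private perspective does not.
    """
    if not 0 <= lag_weight <= 1:
        raise ValueError("lag weight out of range")
    spill = hp.spillover_multiplier if social else 1.0
    cases: dict[str, float] = {}
    deaths: dict[str, float] = {}
    for d in DISEASES:
        n = exposed_persons[d]
        cases[d] = n * hp.incidence[d] * reductions[d] * lag_weight * spill
        deaths[d] = n * hp.mortality[d] * reductions[d] * lag_weight * spill
    return cases, deaths


def yll_per_death(life_expectancy: float, discount: float) -> float:
    """Discounted years of life lost per death.

    Continuous discounting over remaining life expectancy L:
    ``(1 - exp(-r L)) / r``, with limit L as r → 0.
    """
    if not 0 <= discount < 1:
        raise ValueError("discount must be in [0, 1)")
    if discount == 0:
        return life_expectancy
    return (1.0 - math.exp(-discount * life_expectancy)) / discount


def dalys_avoided(
    cases: dict[str, float],
    deaths: dict[str, float],
    hp: HealthParams,
    discount: float,
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-disease (YLL, YLD) for one year's avoided burden."""
    yll = {
        d: deaths[d] * yll_per_death(hp.life_expectancy_remaining[d], discount)
        for d in DISEASES
    }
    yld = {d: cases[d] * hp.daly_weight[d] * hp.morbidity_duration[d] for d in DISEASES}
    return yll, yld


@dataclass
class HealthBenefit:
    """One year's avoided health burden and its monetization, per disease."""

    cases: dict[str, float] = field(default_factory=dict)
    deaths: dict[str, float] = field(default_factory=dict)
    yll: dict[str, float] = field(default_factory=dict)
    yld: dict[str, float] = field(default_factory=dict)
    coi_savings_public: float = 0.0
    coi_savings_private: float = 0.0
    monetized_morbidity: float = 0.0
    monetized_mortality: float = 0.0

    @property
    def dalys(self) -> float:
        return sum(self.yll.values()) + sum(self.yld.values())

    @property
    def total_money(self) -> float:
        return self.monetized_morbidity + self.monetized_mortality


def monetize_health(
    cases: dict[str, float],
    deaths: dict[str, float],
    yll: dict[str, float],
    yld: dict[str, float],
    econ: EconomicParams,
) -> HealthBenefit:
    """Attach money values: VSL for deaths, cost-of-illness plus DALY value
    for morbidity.  Public COI savings are tracked separately so they can be
    netted against government cost."""
    coi_pub = sum(cases[d] * econ.coi_public_per_case[d] for d in DISEASES)
    coi_priv = sum(cases[d] * econ.coi_private_per_case[d] for d in DISEASES)
    morbidity = coi_pub + coi_priv + sum(yld.values()) * econ.value_per_daly
    mortality = sum(deaths.values()) * econ.vsl
    return HealthBenefit(
        cases=cases,
        deaths=deaths,
        yll=yll,
        yld=yld,
        coi_savings_public=coi_pub,
        coi_savings_private=coi_priv,
        monetized_morbidity=morbidity,
        monetized_mortality=mortality,
    )


def yearly_health_benefit(
    covered_households: float,
    children_per_household: float,
    adults_per_household: float,
    z_pre: float,
    z_post: float,
    hp: HealthParams,
    econ: EconomicParams,
    discount: float,
    lag_weight: float,
    social: bool = True,
) -> HealthBenefit:
    """End-to-end health benefit for one year of a transition."""
    reductions = disease_reductions(z_pre, z_post, hp)
    exposed = {
        d: covered_households
        * (children_per_household if d in CHILD_DISEASES else adults_per_household)
        for d in DISEASES
    }
    cases, deaths = avoided_burden(exposed, hp, reductions, lag_weight, social=social)
    yll, yld = dalys_avoided(cases, deaths, hp, discount)
    return monetize_health(cases, deaths, yll, yld, econ)
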