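"""Environmental impact: emission changes, climate benefit, ecosystem benefit.

Emission deltas are positive for reductions.  CO2 from biomass fuels counts
only its non-renewable fraction (fNRB); fossil CO2 counts in full.  Climate
benefits value CO2-equivalent reductions at the social cost of carbon under
either the basic (Kyoto gases) or the full pollutant basket, where organic
carbon carries a negative warming potential (reducing OC emissions is a
climate cost).  Reduced woodfuel harvest is valued at the tree replacement
cost on its non-renewable fraction.
"""

from __future__ import annotations

from .constants import BASIC_BASKET, FULL_BASKET, POLLUTANTS
from .params import EnvironmentParams, StoveFuelParams


def emission_delta(
    baseline: StoveFuelParams,
    new: StoveFuelParams,
    households: float,
    usage_rate: float,
    fnrb: float,
) -> dict[str, float]:
    """Annual emission reduction (tonnes/year, positive = reduction) per
    pollutant for ``households`` adopters at a given usage rate.

    The biomass-CO2 adjustment applies fNRB to each side's CO2 according to
    whether that side's fuel is biomass.
    """
    if households < 0:
        raise ValueError("households must be nonnegative")
    if not 0 <= usage_rate <= 1:
        raise ValueError("usage_rate must be in [0, 1]")
    delta: dict[str, float] = {}
    for p in POLLUTANTS:
        old_g = baseline.annual_fuel_use * baseline.emission_factor[p]
        new_g = new.annual_fuel_use * new.emission_factor[p]
        if p == "co2":
            if baseline.fuel_is_biomass:
                old_g *= fnrb
            if new.fuel_is_biomass:
                new_g *= fnrb
        delta[p] = households * usage_rate * (old_g - new_g) / 1e6  # g → t
    return delta


def climate_benefit(delta: dict[str, float], env: EnvironmentParams) -> float:
    """US$/year value of an emission delta under the configured basket."""
    basket = BASIC_BASKET if env.basket == "basic" else FULL_BASKET
    return sum(delta[p] * env.gwp[p] * env.scc for p in basket)


def biomass_saved(
    baseline: StoveFuelParams, new: StoveFuelParams, households: float, usage_rate: float
) -> float:
    """kg/year of woodfuel harvest avoided by the transition."""
    old = baseline.annual_fuel_use if baseline.fuel_is_biomass else 0.0
    newer = new.annual_fuel_use if new.fuel_is_biomass else 0.0
    return households * usage_rate * (old - newer)


def ecosystem_benefit(
    biomass_saved_kg: float, fnrb: float, tree_replacement_cost: float
) -> float:
    """US$/year value of avoided non-renewable biomass harvest."""
    if fnrb < 0 or fnrb > 1:
        raise ValueError("fnrb must be in [0, 1]")
    if tree_replacement_cost < 0:
        raise ValueError("tree_replacement_cost must be nonnegative")
    return biomass_saved_kg * fnrb * tree_replacement_cost


def yearly_environment_benefit(
    baseline: StoveFuelParams,
    new: StoveFuelParams,
    households: float,
    usage_rate: float,
    env: EnvironmentParams,
) -> tuple[float, float, dict[str, float]]:
    """(climate US$/yr, ecosystem US$/yr, per-pollutant delta t/yr)."""
    delta = emission_delta(baseline, new, households, usage_rate, env.fnrb)
    climate = climate_benefit(delta, env)
    eco = ecosystem_benefit(
        biomass_saved(baseline, new, households, usage_rate),
        env.fnrb,
        env.tree_replacement_cost,
    )
    return climate, eco, delta
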