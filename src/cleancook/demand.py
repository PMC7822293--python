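"""Technology demand and policy-instrument response.

Stove demand is linear in price and summarised by three parameters: the
maximum price anyone would pay (``p_max``, where uptake is zero), the maximum
achievable coverage (``c_max``), and the saturation price (``p_sat``) at or
below which coverage reaches that maximum.  Financing and behaviour-change
interventions pivot the inverse demand outward, scaling total willingness to
pay; fuel subsidies act on uptake through a constant price elasticity; a ban
forces coverage and is charged a consumer-surplus loss.
"""

from __future__ import annotations

import math

from pydantic import BaseModel, Field, model_validator


class DemandCurve(BaseModel):
    """Linear stove demand: coverage as a function of one-time stove price.

    Uptake is ``c_max`` for prices at or below ``p_sat``, falls linearly to
    zero at ``p_max``, and is zero for any price at or above ``p_max`` (the
    adoption interval is half-open at ``p_max``).
    """

    p_max: float = Field(gt=0, description="price (US$) at which uptake reaches zero")
    p_sat: float = Field(
        ge=0, default=0.0, description="price (US$) at/below which coverage saturates"
    )
    c_max: float = Field(gt=0, le=1, description="maximum achievable coverage fraction")

    @model_validator(mode="after")
    def _check_prices(self) -> "DemandCurve":
        if not self.p_sat < self.p_max:
            raise ValueError(f"p_sat ({self.p_sat}) must be below p_max ({self.p_max})")
        return self


class FuelDemandCurve(DemandCurve):
    """Linear demand over a recurrent (annual) fuel price, used for bans."""

    source: str = "synthetic"


def uptake_at_price(curve: DemandCurve, price: float) -> float:
    """Coverage fraction achieved at a given stove price.

    Continuous and nonincreasing in price; 0 at and above ``p_max``,
    ``c_max`` at and below ``p_sat``.
    """
    if price < 0:
        raise ValueError("price must be nonnegative")
    if price >= curve.p_max:
        return 0.0
    if price <= curve.p_sat:
        return curve.c_max
    return curve.c_max * (curve.p_max - price) / (curve.p_max - curve.p_sat)


def inverse_demand(curve: DemandCurve, coverage: float) -> float:
    """Willingness-to-pay price at a given coverage in ``[0, c_max]``."""
    if not 0 <= coverage <= curve.c_max:
        raise ValueError("coverage outside [0, c_max]")
    return curve.p_max - (coverage / curve.c_max) * (curve.p_max - curve.p_sat)


def wtp_area(curve: DemandCurve) -> float:
    """Total willingness to pay: area under inverse demand over [0, c_max].

    Closed form for the linear curve: ``c_max * (p_max + p_sat) / 2``.
    """
    return curve.c_max * (curve.p_max + curve.p_sat) / 2.0


def apply_wtp_pivot(curve: DemandCurve, boost: float) -> DemandCurve:
    """Pivot the inverse demand outward, scaling every WTP price by (1+boost).

    Coverage capacity ``c_max`` is unchanged; adoption begins at a strictly
    higher price for positive boosts, and the area under the inverse demand
    (total WTP) scales by exactly ``1 + boost``.  Financing uses a default
    boost of 0.40, behaviour-change communication 0.10.
    """
    if boost < 0:
        raise ValueError("boost must be nonnegative")
    return curve.model_copy(
        update={"p_max": (1 + boost) * curve.p_max, "p_sat": (1 + boost) * curve.p_sat}
    )


def stove_subsidy_uptake(curve: DemandCurve, stove_price: float, subsidy: float) -> float:
    """Uptake when households face ``(1 - subsidy)`` of the stove price."""
    if not 0 <= subsidy <= 1:
        raise ValueError("subsidy must be in [0, 1]")
    return uptake_at_price(curve, (1 - subsidy) * stove_price)


def fuel_subsidy_multiplier(cost_ratio: float, elasticity: float = -1.0) -> float:
    """Uptake multiplier from a change in recurrent fuel cost.

    Constant-elasticity response: ``cost_ratio ** elasticity``.  With the
    default unit elasticity (-1), halving the recurrent cost doubles uptake.
    """
    if cost_ratio <= 0:
        raise ValueError("cost_ratio must be positive")
    if elasticity >= 0:
        raise ValueError("elasticity must be negative")
    return cost_ratio**elasticity


def fuel_subsidized_uptake(
    base_uptake: float, c_max: float, cost_ratio: float, elasticity: float = -1.0
) -> float:
    """Apply the fuel-subsidy demand response, capped at maximum coverage."""
    return min(c_max, base_uptake * fuel_subsidy_multiplier(cost_ratio, elasticity))


def consumer_surplus(curve: DemandCurve, price: float) -> float:
    """Consumer surplus at a price: area between inverse demand and the price
    over the adopted quantity.  Closed form for the linear curve."""
    if price < 0:
        raise ValueError("price must be nonnegative")
    if price >= curve.p_max:
        return 0.0
    if price >= curve.p_sat:
        q = uptake_at_price(curve, price)
        return 0.5 * q * (curve.p_max - price)
    # saturated region: full triangle plus the rectangle down to the price
    return 0.5 * curve.c_max * (curve.p_max - curve.p_sat) + curve.c_max * (
        curve.p_sat - price
    )


def ban_outcome(
    fuel_curve: FuelDemandCurve,
    banned_fuel_price: float,
    substitute_cost: float,
    substitute_curve: DemandCurve | None = None,
) -> tuple[float, float]:
    """Coverage and per-household welfare loss from banning a fuel.

    Coverage is forced to the substitute technology's maximum (``c_max`` of
    ``substitute_curve``, defaulting to the banned-fuel curve's own).  The
    consumer-surplus loss is the surplus enjoyed on the banned fuel at its
    price net of the surplus available on the substitute at its cost, floored
    at zero (a strictly better substitute implies no loss).
    """
    sub = substitute_curve if substitute_curve is not None else fuel_curve
    lost = consumer_surplus(fuel_curve, banned_fuel_price)
    gained = consumer_surplus(sub, substitute_cost)
    return sub.c_max, max(0.0, lost - gained)


def wtp_area_numeric(curve: DemandCurve, n: int = 100_001) -> float:
    """Trapezoid-rule WTP area; numerical cross-check for :func:`wtp_area`."""
    import numpy as np

    q = np.linspace(0.0, curve.c_max, n)
    p = curve.p_max - (q / curve.c_max) * (curve.p_max - curve.p_sat)
    return float(np.trapezoid(p, q))


def implied_elasticity(
    base_uptake: float, c_max: float, ratio_a: float, ratio_b: float, elasticity: float = -1.0
) -> float:
    """Arc elasticity implied by the fuel-subsidy response between two
    relative cost levels, measured as a log-ratio (valid in the uncapped
    region)."""
    u_a = fuel_subsidized_uptake(base_uptake, c_max, ratio_a, elasticity)
    u_b = fuel_subsidized_uptake(base_uptake, c_max, ratio_b, elasticity)
    return math.log(u_b / u_a) / math.log(ratio_b / ratio_a)
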