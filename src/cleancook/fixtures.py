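"""Synthetic parameter-set generator.

Emits internally consistent, fully validated parameter sets.  The
``nepal_like`` profile mirrors the published setting qualitatively: 74% of
households cook on traditional firewood stoves, the LPG stove costs US$39 at
full price, and the LPG demand curve is calibrated so that nobody adopts at
full price or at a 60% subsidy while adoption rises steeply between 70% and
100% subsidy.  All values are synthetic stand-ins chosen to be realistic for
a South Asian low-income setting; none are the original default database.

The generator is a pure function of ``(seed, profile)``: the seed drives a
small jitter on epidemiological and cost-of-illness rates (parameters a user
would re-estimate locally), while structurally pinned quantities (demand
curves, policy effectiveness, elasticity) are fixed.
"""

from __future__ import annotations

from typing import Literal

import numpy as np

from .demand import DemandCurve, FuelDemandCurve
from .params import (
    BaselineCooking,
    Demography,
    EconomicParams,
    EnvironmentParams,
    HealthParams,
    IERParams,
    InterventionParams,
    ParameterSet,
    ProgramUnitCosts,
    StoveFuelParams,
)

Profile = Literal["nepal_like", "minimal"]


def _ef(co2=0.0, co=0.0, n2o=0.0, ch4=0.0, bc=0.0, oc=0.0) -> dict[str, float]:
    return {"co2": co2, "co": co, "n2o": n2o, "ch4": ch4, "bc": bc, "oc": oc}


def _stove_fuel_table() -> dict[str, StoveFuelParams]:
    """Per-technology stove/fuel characteristics (synthetic, plausible)."""
    return {
        "traditional_biomass": StoveFuelParams(
            stove_price=3.0, fuel_price=0.02, annual_fuel_use=2400.0,
            stove_lifespan=2, efficiency=0.12,
            emission_factor=_ef(co2=1520, co=70, n2o=0.2, ch4=6.0, bc=0.8, oc=3.5),
            kitchen_pm25=600.0, learning_hours=0.0, maintenance_cost=1.0,
            cook_hours_per_day=4.0, collection_hours_per_week=8.0,
            fuel_is_biomass=True,
        ),
        "improved_nd_biomass": StoveFuelParams(
            stove_price=15.0, fuel_price=0.02, annual_fuel_use=1700.0,
            stove_lifespan=3, efficiency=0.22,
            emission_factor=_ef(co2=1520, co=55, n2o=0.18, ch4=4.5, bc=0.7, oc=2.5),
            kitchen_pm25=280.0, learning_hours=5.0, maintenance_cost=2.0,
            cook_hours_per_day=3.2, collection_hours_per_week=5.5,
            fuel_is_biomass=True,
        ),
        "forced_draft_biomass": StoveFuelParams(
            stove_price=40.0, fuel_price=0.02, annual_fuel_use=1200.0,
            stove_lifespan=4, efficiency=0.32,
            emission_factor=_ef(co2=1520, co=35, n2o=0.15, ch4=3.0, bc=0.35, oc=1.2),
            kitchen_pm25=140.0, learning_hours=8.0, maintenance_cost=3.0,
            cook_hours_per_day=2.8, collection_hours_per_week=4.0,
            fuel_is_biomass=True,
        ),
        "chimney_biomass": StoveFuelParams(
            stove_price=25.0, fuel_price=0.02, annual_fuel_use=2000.0,
            stove_lifespan=4, efficiency=0.15,
            emission_factor=_ef(co2=1520, co=65, n2o=0.2, ch4=5.5, bc=0.75, oc=3.2),
            kitchen_pm25=250.0, learning_hours=3.0, maintenance_cost=3.0,
            cook_hours_per_day=3.8, collection_hours_per_week=7.0,
            fuel_is_biomass=True,
        ),
        "traditional_charcoal": StoveFuelParams(
            stove_price=5.0, fuel_price=0.25, annual_fuel_use=900.0,
            stove_lifespan=2, efficiency=0.18,
            emission_factor=_ef(co2=2400, co=200, n2o=0.2, ch4=7.0, bc=1.0, oc=1.3),
            kitchen_pm25=300.0, learning_hours=0.0, maintenance_cost=1.0,
            cook_hours_per_day=3.5, collection_hours_per_week=1.0,
            fuel_is_biomass=True,
        ),
        "improved_charcoal": StoveFuelParams(
            stove_price=18.0, fuel_price=0.25, annual_fuel_use=600.0,
            stove_lifespan=3, efficiency=0.28,
            emission_factor=_ef(co2=2400, co=150, n2o=0.18, ch4=5.0, bc=0.8, oc=1.0),
            kitchen_pm25=180.0, learning_hours=4.0, maintenance_cost=2.0,
            cook_hours_per_day=3.0, collection_hours_per_week=1.0,
            fuel_is_biomass=True,
        ),
        "biomass_pellet": StoveFuelParams(
            stove_price=45.0, fuel_price=0.15, annual_fuel_use=800.0,
            stove_lifespan=4, efficiency=0.35,
            emission_factor=_ef(co2=1600, co=20, n2o=0.1, ch4=1.0, bc=0.1, oc=0.3),
            kitchen_pm25=70.0, learning_hours=10.0, maintenance_cost=3.0,
            cook_hours_per_day=2.5, collection_hours_per_week=0.0,
            fuel_is_biomass=True,
        ),
        "biogas": StoveFuelParams(
            # digester-based; feedstock is dung, no woodfuel harvest and the
            # combustion CO2 is fully biogenic
            stove_price=350.0, fuel_price=0.0, annual_fuel_use=500.0,
            stove_lifespan=15, efficiency=0.55,
            emission_factor=_ef(co2=0.0, co=1.0, ch4=0.5),
            kitchen_pm25=40.0, learning_hours=12.0, maintenance_cost=8.0,
            cook_hours_per_day=2.2, collection_hours_per_week=0.5,
            fuel_is_biomass=False,
        ),
        "lpg": StoveFuelParams(
            stove_price=39.0, fuel_price=1.3, annual_fuel_use=110.0,
            stove_lifespan=7, efficiency=0.55,
            emission_factor=_ef(co2=3000, co=15, n2o=0.1, ch4=0.5, bc=0.02, oc=0.02),
            kitchen_pm25=40.0, learning_hours=6.0, maintenance_cost=2.0,
            cook_hours_per_day=2.0, collection_hours_per_week=0.0,
            fuel_is_biomass=False,
        ),
        "electric": StoveFuelParams(
            stove_price=60.0, fuel_price=0.07, annual_fuel_use=600.0,
            stove_lifespan=8, efficiency=0.75,
            emission_factor=_ef(),  # no direct household emissions
            kitchen_pm25=20.0, learning_hours=8.0, maintenance_cost=2.0,
            cook_hours_per_day=1.9, collection_hours_per_week=0.0,
            fuel_is_biomass=False,
        ),
        "ethanol": StoveFuelParams(
            stove_price=35.0, fuel_price=0.9, annual_fuel_use=170.0,
            stove_lifespan=6, efficiency=0.50,
            emission_factor=_ef(co2=100, co=5, ch4=0.2),
            kitchen_pm25=45.0, learning_hours=6.0, maintenance_cost=2.0,
            cook_hours_per_day=2.0, collection_hours_per_week=0.0,
            fuel_is_biomass=False,
        ),
        "kerosene": StoveFuelParams(
            stove_price=10.0, fuel_price=1.0, annual_fuel_use=130.0,
            stove_lifespan=4, efficiency=0.45,
            emission_factor=_ef(co2=3100, co=30, n2o=0.1, ch4=1.0, bc=0.6, oc=0.2),
            kitchen_pm25=150.0, learning_hours=2.0, maintenance_cost=2.0,
            cook_hours_per_day=2.5, collection_hours_per_week=0.0,
            fuel_is_biomass=False,
        ),
        "coal": StoveFuelParams(
            stove_price=8.0, fuel_price=0.15, annual_fuel_use=1100.0,
            stove_lifespan=3, efficiency=0.20,
            emission_factor=_ef(co2=2200, co=120, n2o=0.3, ch4=4.0, bc=0.5, oc=0.8),
            kitchen_pm25=500.0, learning_hours=0.0, maintenance_cost=1.0,
            cook_hours_per_day=3.5, collection_hours_per_week=1.0,
            fuel_is_biomass=False,
        ),
    }


def _stove_demand() -> dict[str, DemandCurve]:
    # LPG curve calibrated so that uptake is zero at the US$39 full price and
    # at a 60% subsidy (household price 15.60), and rises steeply thereafter.
    return {
        "lpg": DemandCurve(p_max=15.45, p_sat=3.63, c_max=1.0),
        "improved_nd_biomass": DemandCurve(p_max=6.0, p_sat=1.0, c_max=0.95),
        "forced_draft_biomass": DemandCurve(p_max=14.0, p_sat=3.0, c_max=0.9),
        "chimney_biomass": DemandCurve(p_max=10.0, p_sat=2.0, c_max=0.9),
        "improved_charcoal": DemandCurve(p_max=8.0, p_sat=2.0, c_max=0.9),
        "biomass_pellet": DemandCurve(p_max=16.0, p_sat=4.0, c_max=0.85),
        "biogas": DemandCurve(p_max=120.0, p_sat=25.0, c_max=0.6),
        "electric": DemandCurve(p_max=22.0, p_sat=5.0, c_max=0.9),
        "ethanol": DemandCurve(p_max=12.0, p_sat=3.0, c_max=0.8),
    }


def _fuel_demand() -> dict[str, FuelDemandCurve]:
    # demand over the annual recurrent fuel cost, used only for ban welfare
    return {
        "traditional_biomass": FuelDemandCurve(p_max=120.0, p_sat=0.0, c_max=1.0),
        "traditional_charcoal": FuelDemandCurve(p_max=300.0, p_sat=30.0, c_max=0.9),
        "kerosene": FuelDemandCurve(p_max=200.0, p_sat=20.0, c_max=0.9),
        "coal": FuelDemandCurve(p_max=180.0, p_sat=20.0, c_max=0.9),
        "lpg": FuelDemandCurve(p_max=260.0, p_sat=40.0, c_max=1.0),
    }


def generate_fixture(seed: int, profile: Profile = "nepal_like") -> ParameterSet:
    """Deterministically synthesize a validated parameter set.

    ``nepal_like`` is the full-scale study setting; ``minimal`` is a small,
    frictionless variant (tiny population, full usage, no leakage or
    spillover) convenient for analytic cross-checks.
    """
    if profile not in ("nepal_like", "minimal"):
        raise ValueError(f"unknown profile {profile!r}")
    rng = np.random.default_rng(seed)
    minimal = profile == "minimal"

    def jitter(x: float, rel: float = 0.03) -> float:
        if minimal:
            return x
        return float(x * (1 + rng.uniform(-rel, rel)))

    demography = Demography(
        total_population=20_000.0 if minimal else 28_600_000.0,
        household_size=4.6,
        children_u5_per_household=0.45,
    )
    economics = EconomicParams(
        social_discount_rate=0.03,
        shadow_time_fraction=0.5,
        unskilled_wage=0.6,
        value_per_daly=850.0,
        vsl=180_000.0,
        coi_public_per_case={
            "copd": jitter(70.0), "alri": jitter(35.0), "ihd": jitter(120.0),
            "lung_cancer": jitter(150.0), "stroke": jitter(160.0),
        },
        coi_private_per_case={
            "copd": jitter(40.0), "alri": jitter(20.0), "ihd": jitter(80.0),
            "lung_cancer": jitter(110.0), "stroke": jitter(120.0),
        },
    )
    baseline = BaselineCooking(
        fraction_using={
            "traditional_biomass": 0.74,
            "lpg": 0.18,
            "biogas": 0.03,
            "improved_nd_biomass": 0.02,
            "traditional_charcoal": 0.01,
            "kerosene": 0.01,
            "electric": 0.01,
        },
        cook_hours_per_day=4.0,
        fuel_mass_per_year=2400.0,
        collection_hours_per_week=8.0,
    )
    interventions = InterventionParams(
        subsidy_stove=0.0,
        subsidy_fuel=0.25,
        leakage=0.0 if minimal else 0.10,
        financing_boost=0.40,
        bcc_boost=0.10,
        fuel_elasticity=-1.0,
        program_unit_costs=ProgramUnitCosts(
            personnel=300_000.0, training=120_000.0, advertising=200_000.0,
            equipment=80_000.0, promotion_per_adopter=2.0,
        ) if not minimal else ProgramUnitCosts(
            personnel=500.0, training=200.0, advertising=300.0,
            equipment=100.0, promotion_per_adopter=1.0,
        ),
        ramp="default",
        stove_demand=_stove_demand(),
        fuel_demand=_fuel_demand(),
    )
    health = HealthParams(
        incidence={
            "copd": jitter(0.004), "alri": jitter(0.25), "ihd": jitter(0.005),
            "lung_cancer": jitter(0.0004), "stroke": jitter(0.003),
        },
        mortality={
            "copd": jitter(0.0012), "alri": jitter(0.003), "ihd": jitter(0.0016),
            "lung_cancer": jitter(0.0003), "stroke": jitter(0.0012),
        },
        life_expectancy_remaining={
            "copd": 14.0, "alri": 68.0, "ihd": 17.0,
            "lung_cancer": 15.0, "stroke": 16.0,
        },
        daly_weight={
            "copd": 0.28, "alri": 0.13, "ihd": 0.08,
            "lung_cancer": 0.29, "stroke": 0.32,
        },
        morbidity_duration={
            "copd": 9.0, "alri": 0.02, "ihd": 5.5,
            "lung_cancer": 2.5, "stroke": 6.0,
        },
        ier={
            "copd": IERParams(alpha=0.593, gamma=0.00459, delta=0.740, z_cf=7.3),
            "alri": IERParams(alpha=2.445, gamma=0.00665, delta=0.643, z_cf=7.3),
            "ihd": IERParams(alpha=0.879, gamma=0.0472, delta=0.466, z_cf=7.3),
            "lung_cancer": IERParams(alpha=1.310, gamma=0.00442, delta=0.742, z_cf=7.3),
        },
        exposure_adjustment=1.0 if minimal else 0.55,
        usage_rate=1.0 if minimal else 0.80,
        spillover_multiplier=1.0 if minimal else 1.15,
        lag_schedule=[1.0] * 15 if minimal
        else [0.0, 0.0, 0.2, 0.4, 0.6, 0.8] + [1.0] * 9,
    )
    environment = EnvironmentParams(
        tree_replacement_cost=0.04,
        scc=40.0,
        gwp={"co2": 1.0, "co": 1.8, "n2o": 273.0, "ch4": 29.8, "bc": 900.0, "oc": -46.0},
        fnrb=0.42,
        basket="full",
    )
    return ParameterSet(
        demography=demography,
        economics=economics,
        baseline_cooking=baseline,
        interventions=interventions,
        stove_fuel=_stove_fuel_table(),
        health=health,
        environment=environment,
        horizon_years=15,
    )
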