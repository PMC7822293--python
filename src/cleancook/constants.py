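"""Fixed vocabularies: diseases, pollutants, technologies, transition catalog.

The disease list and pollutant list are fixed design choices of the model;
adding members is out of scope.  Technology identifiers key the stove/fuel
parameter maps and the transition catalog.
"""

from __future__ import annotations

# The five health outcomes attributable to fine-particulate household air
# pollution that the model tracks.  Stroke has no integrated exposure-response
# function of its own; its burden reduction is tied to the least-reduced of
# the other four (see health.stroke_reduction).
DISEASES: tuple[str, ...] = ("copd", "alri", "ihd", "lung_cancer", "stroke")

#: Diseases with their own exposure-response parameterisation.
IER_DISEASES: tuple[str, ...] = ("copd", "alri", "ihd", "lung_cancer")

#: Acute lower respiratory infection burden falls on children under five;
#: the remaining conditions on the adult population.
CHILD_DISEASES: frozenset[str] = frozenset({"alri"})

# Climate-forcing pollutants.  Organic carbon (OC) is a net cooling agent and
# carries a negative CO2-equivalence factor.
POLLUTANTS: tuple[str, ...] = ("co2", "co", "n2o", "ch4", "bc", "oc")

#: Kyoto-protocol gases: the "basic" climate-benefit basket.
BASIC_BASKET: tuple[str, ...] = ("co2", "n2o", "ch4")
#: The "full" basket adds carbon monoxide, black carbon and organic carbon.
FULL_BASKET: tuple[str, ...] = ("co2", "n2o", "ch4", "co", "bc", "oc")

TECHNOLOGIES: tuple[str, ...] = (
    "traditional_biomass",
    "improved_nd_biomass",
    "forced_draft_biomass",
    "chimney_biomass",
    "traditional_charcoal",
    "improved_charcoal",
    "biomass_pellet",
    "biogas",
    "lpg",
    "electric",
    "ethanol",
    "kerosene",
    "coal",
)

#: Target fuels for which a recurrent fuel subsidy may be offered.
FUEL_SUBSIDY_ELIGIBLE: frozenset[str] = frozenset(
    {"biomass_pellet", "lpg", "electric", "ethanol"}
)

TRANSITION_GROUPS: tuple[str, ...] = (
    "biomass_to_transitional",
    "biomass_to_clean",
    "kerosene_to_clean",
    "clean_to_clean",
)

# (id, from_tech, to_tech, group) — sixteen transitions in four groups:
# biomass users moving to transitional technologies, biomass users moving to
# clean fuels, kerosene users moving to clean fuels, and one clean fuel to
# another (LPG to electric).
TRANSITION_TABLE: tuple[tuple[int, str, str, str], ...] = (
    (1, "traditional_biomass", "improved_nd_biomass", "biomass_to_transitional"),
    (2, "traditional_biomass", "forced_draft_biomass", "biomass_to_transitional"),
    (3, "traditional_biomass", "chimney_biomass", "biomass_to_transitional"),
    (4, "traditional_charcoal", "improved_charcoal", "biomass_to_transitional"),
    (5, "traditional_biomass", "lpg", "biomass_to_clean"),
    (6, "traditional_biomass", "biogas", "biomass_to_clean"),
    (7, "traditional_biomass", "electric", "biomass_to_clean"),
    (8, "traditional_biomass", "ethanol", "biomass_to_clean"),
    (9, "traditional_biomass", "biomass_pellet", "biomass_to_clean"),
    (10, "traditional_charcoal", "lpg", "biomass_to_clean"),
    (11, "traditional_charcoal", "electric", "biomass_to_clean"),
    (12, "traditional_charcoal", "ethanol", "biomass_to_clean"),
    (13, "kerosene", "lpg", "kerosene_to_clean"),
    (14, "kerosene", "electric", "kerosene_to_clean"),
    (15, "kerosene", "ethanol", "kerosene_to_clean"),
    (16, "lpg", "electric", "clean_to_clean"),
)

DEFAULT_HORIZON: int = 15
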