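# Methods

This note documents the model implemented in `cleancook`: its structure,
assumptions, parameterisation, numerical conventions, and limitations.

## Scope and structure

The model evaluates policy packages that move households from a more
polluting cooking technology to a cleaner one. Sixteen transitions are
supported, in four groups: biomass to transitional technologies (improved
natural-draft, forced-draft and chimney biomass stoves; improved charcoal),
biomass to clean fuels (LPG, biogas, electricity, ethanol, biomass pellets),
kerosene to clean fuels, and LPG to electric. The printed catalog of the
original four groups pins only some memberships; the concrete 16-entry table
in `cleancook.constants` is this package's own consistent enumeration.

A scenario pairs one or more transitions (with **laddering** shares that
split a baseline user population across simultaneous transitions; shares per
baseline technology must sum to 1) with exactly one policy instrument. A
stove subsidy may be stacked on the fuel-subsidy, financing, or
behaviour-change instruments; those three cannot be combined with one
another, and a ban stands alone. Outputs are per-subsidy-level outcome rows:
coverage, PV net public cost (gross government cost minus public
cost-of-illness savings), per-capita public cost over the target population,
DALYs avoided, the cost-effectiveness ratio, and social net benefits in NPV
terms.

## Demand and policy response

Stove demand is linear and summarised by (p_max, c_max, p_sat): coverage is
c_max at or below the saturation price p_sat, falls linearly, and reaches 0
at the choke price p_max. The adoption interval is half-open: uptake at
exactly p_max is 0.

- **Stove subsidy** s: households face (1−s)·price.
- **Financing / BCC**: the inverse demand is pivoted outward by scaling
  every willingness-to-pay price by (1+b), b defaulting to 0.40 (financing)
  and 0.10 (BCC). This is the unique linear transform that both lets
  adoption begin at a proportionally higher price and scales the area under
  the inverse demand (total WTP) by exactly 1+b.
- **Fuel subsidy**: uptake is multiplied by (cost ratio)^ε with constant
  elasticity ε (default −1), capped at c_max. The subsidy is restricted to
  target fuels with a meaningful recurrent price: pellets, LPG, electricity,
  ethanol. The recurrent outlay flows to *all* users of the subsidised fuel,
  including households that used it before the program.
- **Ban**: coverage is forced to the substitute technology's c_max. The
  welfare cost is the consumer surplus enjoyed on the banned fuel at its
  recurrent price, net of the surplus available on the substitute at its
  cost, floored at zero; it is charged annually per covered household. Fuel
  demand curves (over annual recurrent cost) are a separate parameter block.

## Exposure and health

Personal exposure is the kitchen-area PM2.5 concentration times an
exposure-adjustment factor in (0,1], capturing the divergence between
kitchen and personal measurements (including behavioural adjustment as
kitchens get cleaner). Stove stacking enters as a usage rate u: the
post-transition kitchen concentration is u·z_new + (1−u)·z_old. The same
usage rate scales fuel use, emissions, and time savings, so setting u = 0
zeroes every benefit.

Relative risk for COPD, ALRI, IHD and lung cancer follows the integrated
exposure-response form RR(z) = 1 + α(1 − exp(−γ(z−z_cf)^δ)) above a
counterfactual concentration z_cf, with per-disease user-supplied
parameters. The potential impact fraction of moving from RR_pre to RR_post
is (RR_pre − RR_post)/RR_pre. Stroke has no curve of its own; its impact
fraction is the minimum of the other four (applied to impact fractions, not
absolute burdens — a deliberately conservative reading flagged for
sensitivity analysis). ALRI burden falls on the under-five population
(children per household × covered households); the other conditions on the
adult population.

Avoided cases and deaths in year t are population × incidence (or
mortality) × impact fraction × lag(t) × spillover. The lag schedule is a
per-calendar-year vector in [0,1], nondecreasing and reaching 1; the default
rises linearly over the first five years in which adopters exist under the
default ramp. The ambient-air spillover multiplier (≥1) applies in the
social perspective only.

DALYs = YLL + YLD. YLL per death discounts remaining disease-specific life
expectancy L continuously at the social discount rate r: (1 − e^{−rL})/r
(limit L at r = 0); no age weighting. YLD is incidence-based: cases ×
disability weight × duration. Mortality is valued at the VSL; morbidity at
public + private cost of illness per case plus YLD × a per-DALY value.
Public cost-of-illness savings are tracked separately for netting against
government cost. Reported DALY totals are additionally discounted across
years at r, consistent with the money streams.

## Environment

Annual emission deltas per pollutant (CO2, CO, N2O, CH4, BC, OC) are
households × usage × (fuel_old·EF_old − fuel_new·EF_new), in tonnes. CO2
from biomass fuels is scaled by the non-renewable biomass fraction fNRB on
whichever side burns biomass; fossil CO2 counts in full. Climate benefits
value the delta at gwp_p × SCC summed over the configured basket — basic
(CO2, N2O, CH4) or full (adding CO, BC, OC). GWP values are user inputs
(users encode their horizon/weighting choice), constrained only by
gwp[CO2] = 1 and gwp[OC] ≤ 0: organic carbon is a net cooling agent, so
reducing OC emissions scores as a climate cost. Black carbon's health effect
is not modelled separately — it is part of PM2.5 — only its climate role.
Avoided woodfuel harvest × fNRB × tree replacement cost gives the ecosystem
benefit.

## Costs, aggregation, outcome metrics

The horizon is 15 years. The default roll-out ramp is
[0, 0, 1/3, 2/3, 1, …, 1] — two planning years without benefits, then a
third of the target population added per year; "immediate" is all ones. New
adopters are first differences of covered households; each cohort
repurchases its stove every lifespan years within the horizon.

Government costs: fixed annual program costs (personnel, training,
advertising, equipment), a per-adopter promotion cost (the only program cost
that scales with users targeted), stove-subsidy outlays at purchase and
replacement years, and recurrent fuel-subsidy outlays — subsidy flows
inflated by (1 + leakage). Household costs: the unsubsidised stove share,
one-time learning time at the shadow value of time, net maintenance, and the
net recurrent fuel bill (post-subsidy prices, scaled by usage). Time savings
value the change in cooking hours (×365) and collection hours (×52) at
shadow_time_fraction × unskilled wage; collection time is counted once, on
the benefits side.

Discounting is end-of-year with year 1 undiscounted: PV = Σ v_t/(1+r)^{t−1}.
The social account treats subsidies *and their leakage* as transfers:
resource costs (full stove price once, learning, maintenance, net fuel at
pre-subsidy prices, program costs, consumer-surplus loss under a ban) are
set against benefits (monetised health with spillover, time savings,
climate, ecosystem). This makes the social NPV invariant to how the stove
bill is split between government and households at fixed adoption — a
property the test suite asserts. The CER is PV public cost / DALYs avoided,
"n.a." when no DALYs are avoided; the numerator is configurable gross
(default) or net of public cost-of-illness savings, since either convention
appears in practice. A bisection utility locates the stove subsidy at which
social NPV crosses zero.

Laddered component rows are combined by summation (the model is linear in
the target population), with coverage population-weighted and per-capita
cost taken over the union target population.

## Parameter file and synthetic fixtures

Parameters live in one JSON document with seven sections — demography,
economics, baseline_cooking, interventions (including demand curves),
stove_fuel, health, environment — all maps keyed by name, every field
validated (bounds, map completeness over the five diseases and six
pollutants, lag-schedule monotonicity, demand-curve ordering). A flattened
CSV export supports review. Currency is US$ throughout.

No default country database ships with the package. `generate_fixture(seed,
profile)` emits synthetic, internally consistent sets:

- **nepal_like** — a ~28.6M-person setting with 74% of households on
  traditional firewood stoves, a US$39 LPG stove whose demand curve
  (p_max 15.45, p_sat 3.63, c_max 1.0) yields zero uptake at full price and
  at a 60% subsidy and roughly a third of households at 70%, a 3% social
  discount rate, usage rate 0.8, exposure adjustment 0.55, spillover 1.15,
  and plausible South-Asian epidemiology, costs and emission factors. The
  seed jitters locally-estimated rates (incidence, mortality, cost of
  illness) by ±3%; structural values are pinned.
- **minimal** — a 20 000-person frictionless variant (usage 1, exposure
  adjustment 1, no leakage or spillover, flat lag) used for analytic
  cross-checks such as transfer neutrality.

These fixtures emulate the *shape* of real settings — demand thresholds,
burden composition, cost ordering — not any country's measured values, so
passing tests demonstrate correctness of the accounting and response
mechanics, not predictive accuracy for a real population.

## Numerical conventions and edge cases

- Uptake at exactly p_max is 0 (half-open interval); curves require
  p_sat < p_max and c_max ∈ (0,1].
- RR is exactly 1 at or below z_cf and continuous there.
- YLL uses the r → 0 limit explicitly; CER returns a typed "n.a." (`None`,
  serialised as the literal `n.a.`) rather than infinity.
- Stove lifespans are rounded to whole years for the replacement schedule.
- Breakeven search uses Brent's method on [0,1] after a sign-change check;
  no sign change returns `None`.
- All computation is deterministic; the only randomness is the fixture
  generator's seeded jitter.

## Limitations

Static population and epidemiology; no cross-household heterogeneity in
exposure; no cross-price substitution between fuels outside the ban case; no
economies of scale in program delivery (only stove, fuel and promotion costs
scale with users); ambient air pollution's contribution to baseline exposure
is not modelled; private benefits are valued by component (health, time,
fuel) rather than as willingness to pay, so they can diverge from a
welfare-theoretic demand-curve measure.
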