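# cleancook

Cost-benefit decision support for household clean-cooking energy transitions.

Roughly 2.8 billion people cook with polluting fuels — firewood, charcoal,
dung, kerosene, coal — and the resulting household air pollution (HAP) drives
a large burden of respiratory and cardiovascular disease, heavy time costs
for fuel collection and cooking, forest degradation, and climate-forcing
emissions. `cleancook` helps health and energy planners compare policy
packages that accelerate the shift to cleaner stoves and fuels. For any of
sixteen cooking-technology transitions (e.g. traditional firewood stoves →
LPG) under five policy instruments (stove subsidy, fuel subsidy, consumer
financing, behaviour-change communication, ban), it computes over a 15-year
horizon:

1. **government cost**, overall and per capita, net of public cost-of-illness
   savings;
2. **DALYs avoided** and the cost-effectiveness ratio (PV public US$ per DALY
   avoided);
3. **social net benefits** in net-present-value terms.

## Model core

Stove demand is linear in price with three parameters: choke price
*p*<sub>max</sub>, maximum coverage *c*<sub>max</sub>, and saturation price
*p*<sub>sat</sub>. Policy instruments act on this curve: a stove subsidy *s*
moves households to price (1−*s*)·*p*; financing and behaviour-change pivots
scale the inverse demand by (1+*b*) with default boosts of 40% and 10% of
total willingness to pay; a fuel subsidy multiplies uptake by the cost ratio
raised to a constant price elasticity (default −1, so halving the recurrent
cost doubles uptake, capped at *c*<sub>max</sub>); a ban forces coverage and
charges the lost consumer surplus.

Adoption changes personal PM2.5 exposure *z* (kitchen concentration × an
exposure-adjustment factor, with stove stacking as a usage-rate-weighted
mixture). Disease-specific relative risk follows an integrated
exposure-response curve

&nbsp;&nbsp;RR(*z*) = 1 + α·(1 − e<sup>−γ(*z*−*z*<sub>cf</sub>)<sup>δ</sup></sup>)

for COPD, ALRI (children under five), IHD and lung cancer; stroke is assigned
the least-reduced impact fraction of the other four. Avoided deaths are
valued by the VSL and converted to YLL = (1−e<sup>−rL</sup>)/r per death;
avoided cases contribute YLD = disability weight × duration, plus
public/private cost-of-illness savings. Emission changes (CO2, CO, N2O, CH4,
BC, OC — organic carbon with a negative warming potential) are valued at the
social cost of carbon under a basic (Kyoto) or full basket, with biomass CO2
scaled by the non-renewable fraction fNRB, which also prices avoided woodfuel
harvest at the tree replacement cost. All streams are discounted end-of-year
(year 1 undiscounted) under a roll-out ramp of two planning years plus a
three-year phase-in; subsidies (and their leakage) are treated as transfers
in the social account.

## Worked example

```python
from cleancook import generate_fixture
from cleancook.params import PolicySpec
from cleancook.scenario import LadderComponent, Scenario, subsidy_sweep, sweep_table

params = generate_fixture(1, "nepal_like")   # synthetic Nepal-like setting
sc = Scenario(
    transitions=[LadderComponent(transition_id=5, share=1.0)],  # firewood → LPG
    policy=PolicySpec(instrument="stove_subsidy"),
    subsidy_grid=[0.0, 0.6, 0.7, 0.85, 1.0],
)
print(sweep_table(subsidy_sweep(sc, params), 5).to_string(
    float_format=lambda v: f"{v:,.2f}"))
```

```
                                  0%           60%               70%               85%              100%
target_coverage                 0.00          0.00              0.32              0.81              1.00
pv_net_public_cost      8,607,251.20  8,607,251.20     63,676,727.81    189,494,654.30    280,463,491.06
per_capita_public_cost          0.41          0.41              3.01              8.95             13.25
pv_public_coi_savings           0.00          0.00     20,354,676.27     52,107,971.24     64,157,939.59
dalys_avoided                   0.00          0.00        540,944.78      1,384,818.63      1,705,057.93
cer                             n.a.          n.a.            155.34            174.47            202.12
pv_social_net_benefits -8,607,251.20 -8,607,251.20 10,053,233,394.23 25,749,704,801.09 31,706,314,463.18
```

At 0% and 60% subsidy the household price of the US$39 LPG stove stays above
the choke price, so coverage is zero, no DALYs are avoided (CER is "n.a."),
and the program's fixed administrative costs make the social NPV negative.
From a 70% subsidy upward adoption rises to full coverage; government cost,
DALYs avoided and social net benefits grow monotonically with the subsidy.
The breakeven utility places the subsidy at which social NPV turns positive
just above 60%:

```python
from cleancook import find_breakeven_subsidy
from cleancook.params import get_transition
find_breakeven_subsidy(params, get_transition(5), PolicySpec(instrument="stove_subsidy"))
# 0.6039...
```

A command-line interface wraps the same library:

```bash
cleancook fixture --seed 1 --out params.json
cleancook validate params.json
cleancook run --params params.json --scenario scenario.json --out-dir results
cleancook sweep --params params.json --scenario scenario.json --out-dir results
cleancook demand plot --params params.json --tech lpg --out curve.csv
```

Exit codes: 0 success, 2 validation failure, 3 runtime failure.

## Scope

The package ships no country default database: all parameters are supplied by
the user in a documented JSON schema (see `docs/methods.md`), and
`generate_fixture` emits internally consistent synthetic parameter sets for
testing and exploration. The model is static — population, adoption dynamics
beyond the ramp, and disease rates do not evolve over time.
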