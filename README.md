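# heatburden

A generic, scalable model of the **health and climate impacts of a city's
building stock**: how floor area, renovation policy and heating-fuel choices
translate into heating-energy demand, CO₂ and fine-particle (PM₂.₅)
emissions, population exposure, and finally premature deaths and
disability-adjusted life years (DALYs).

It is written for city environmental and health authorities (and the
modellers who support them) who need to compare climate-mitigation policies —
"renovate 4.5 % of old buildings per year", "replace half of the peat in the
district-heat plant with wood chips" — on both climate and public-health
terms, with uncertainty made explicit.

## The model

Everything is a long-format **indexed table**: a value column plus named
index columns (Time, Built era, Building type, Heating type, Renovation
state, Fuel, Pollutant, …). Arithmetic between tables is an inner join on
shared index columns with broadcasting over the rest, so extra dimensions —
a Monte-Carlo `Iteration` index, or one column per policy decision — flow
through the whole chain without touching model code. The chain is:

1. **Stock dynamics** — annual time step; new construction enters the
   current decade cohort; a fraction *r* of unrenovated, over-30-year-old
   floor area is renovated each year and split across renovation depths.
   Renovation conserves floor area exactly.
2. **Energy demand** — heat (kWh/a) = floor area × specific demand, where
   specific demand depends on era and drops by a per-depth saving after
   renovation (floored at 20 kWh/m²/a).
3. **Fuel and emissions** — delivered heat × conversion efficiency × fuel-mix
   share = fuel input (MWh/a); × emission factor (kg/MWh) = emissions (t/a)
   of CO2_fossil, CO2_total and PM2.5. Peat counts as fossil
   (380 kg CO₂/MWh); wood counts zero fossil but 420 kg/MWh of real stack CO₂.
4. **Exposure and health** — with intake fraction *iF* (inhaled/emitted
   mass), population *P*, breathing rate *BR*:

   ΔC = E·iF / (P·BR·365.25)  [µg/m³],
   RR = exp(ln(RR₁₀)·ΔC/10),
   deaths = P·M·(RR−1)/RR,
   DALY = deaths·YLL.

5. **Scenarios and uncertainty** — policies are data, not code: a decision
   table expands targeted inputs along new scenario index columns (BAU always
   reproduces the untouched run). Uncertain inputs carry distributions;
   Monte-Carlo sampling adds the `Iteration` index; a deterministic mode uses
   medians. Climate and health outputs are combined at 15 €/t CO₂ and
   50 000 €/DALY, and each uncertain input is ranked by the absolute Spearman
   correlation between its draws and the monetized total (absolute, or
   incremental versus BAU).

Because real city datasets live on external project servers, the package
ships **synthetic presets** that emulate their structure: `kuopio_like`
(88 % district heating, ~800 GWh/a, stock doubling by 2050, peat→wood fuel
policy, three renovation policies), `basel_like`, the reduced `kuopio_mc`
for sampling runs, and the one-stratum `mini` city whose output has a
closed form used as a test oracle.

## Worked example

```bash
heatburden synth --preset kuopio_like -o city
heatburden run -c city/config.yaml
heatburden report -o city/output
```

or in Python:

```python
from heatburden import synth, run_model

b = synth.generate_city(synth.kuopio_like_template())
out = run_model(b.inputs, decisions=b.decisions, weights=b.weights)
d = out.daly.data
print(d[d.Time == 2030].pivot_table(index="Renovation_policy",
                                    columns="Fuel_policy", values="Result"))
```

which prints the 2030 burden (DALY/a) for the 3 × 2 policy factorial:

```
Fuel_policy              BAU    Biofuel
Renovation_policy
Active             19.085934  18.730851
BAU                19.839713  19.470620
Efficient          18.190729  17.852286
```

Read: business-as-usual heating causes ≈ 19.8 DALY/a of PM₂.₅ mortality
burden in 2030; the deepest renovation policy combined with the peat→wood
fuel switch lowers it to ≈ 17.9 DALY/a (−10 %). The same run's emission
tables show the fuel switch cutting regulated fossil CO₂ by ≈ 43 % while
total CO₂ rises only ≈ 8 % — the policy mainly relabels the carbon, which is
exactly the tension it is meant to expose.

Monte-Carlo importance (`heatburden importance -c city/config.yaml`) ranks
the exposure-response slope far above every other sampled input
(|ρ| ≈ 0.92–0.93 versus ≤ 0.26), with the wood life-cycle CO₂ input — which
cannot move the fossil-CO₂ + DALY outcome — indistinguishable from zero.

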