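# Methods

This note documents the model behind `heatburden`: its assumptions, the
parameters that matter, what the synthetic city presets do and do not
emulate, and the numerical choices made where the design was genuinely open.

## Indexed tables and the scenario engine

All quantities are long-format tables: named index columns (categorical or
integer-year), one numeric `Result` column, and a free-text unit. Binary
arithmetic is an inner join on the shared index columns, broadcasting over
columns present in only one operand. Rows whose shared-index values find no
partner are dropped and the count is logged (a warning-level alternative to
erroring; disjoint shared indices *are* an error, since they indicate a
wiring mistake rather than partial coverage). Units are combined naively as
strings ("m2 × kWh/m2/a" keeps the left unit when the right is
dimensionless); unit checking is advisory, not blocking — the pipeline
restamps units at each stage boundary.

Policies are data. A decision table lists (decision, option, target table,
cell selector, change, value) rows; applying it duplicates each targeted
table along a new index column per decision. The `BAU` level is always the
untouched input, which yields the central invariant of the engine: the BAU
slice of any downstream output equals the no-policy run to machine
precision. Changes within one option apply in row order; `multiply`/`add` do
not commute with `replace`, so order in the file is meaningful. A selector
matching zero rows is an error — a silently inert policy is a modelling
hazard, not a convenience.

Aggregation (`sum`/`mean`) never silently drops the `Iteration` index
(explicit flag required) and always retains decision columns.

## Stock dynamics

Floor area (m²) is indexed by Time, Built (decade of construction, labelled
by start year), Building type, Heating type and Renovation state
(`none`, `windows`, `windows_sheath_tech`, `total_sheath`, ordered by
depth). The annual step: carry forward, add new construction (entering the
current decade, unrenovated), then renovate `rate` × eligible area, where
eligible means unrenovated and older than `age_threshold` (default 30)
years, measured conservatively from the era *start* year. Moved area is
split across depths by `depth_shares` (must sum to 1). Total floor area is
conserved exactly at every step.

Choices made where the data model was open:

- **Demolition** defaults to zero (not part of the scenario set the model is
  built for) but is accepted as an optional per-year fraction.
- **Renovated stock never re-enters eligibility** within the horizon; a
  second deep renovation inside 40 years is unrealistic.
- The renovation **rate base** is the currently-unrenovated over-threshold
  area (so the unrenovated fraction of a static stock decays geometrically,
  (1−r)ᵏ — used as a test oracle). An alternative base — all over-threshold
  area, capped by the unrenovated pool — is available via
  `rate_base="all_over_threshold"`.
- An exhaust-everything policy ("renovate all old buildings by the horizon")
  is represented as a high constant rate (0.10/a leaves < 2 % of the
  eligible pool after 40 years) rather than a time-varying schedule.

## Energy demand

Heat demand = floor area × specific demand (kWh/m²/a). Specific demand
depends on construction era (older is thirstier) and drops after renovation
by a per-depth saving, floored at 20 kWh/m²/a so deep renovation of an
already-efficient cohort cannot produce nonsense. New construction gets its
own low-energy demand class rather than a "renovated" label, which is also
why the renovated-share statistic counts post-2010 construction as
energy-efficient. Only heating energy is modelled — no hourly load curves,
no cooling, no appliance electricity. Climate (degree-day) variation between
years is not modelled; a global scalar multiplier on demand is exposed for
users who want it.

## Fuel use and emissions

Fuel input = heat × conversion efficiency (MWh fuel per MWh delivered heat,
per heating type) × fuel-mix share. Mix shares must sum to 1 per heating
type and anchor year; mixes given at anchor years are linearly interpolated
to model years and held constant outside the anchors. Emissions = fuel ×
factor (kg/MWh) / 1000, for three pollutants: `CO2_fossil` (the regulated
quantity: peat 380 kg/MWh, wood 0), `CO2_total` (includes biogenic stack
carbon: wood 420 kg/MWh) and `PM2.5`. The factor table enforces
CO2_fossil ≤ CO2_total per fuel.

All combustion emissions of a cogenerating district-heat plant are
attributed to the delivered heat; the electricity forgone when heat demand
falls is bought from outside the city and its emissions are out of the
system boundary. Secondary wood heating in detached houses is acknowledged
as a real PM source but is off by default (it can be added as an extra
heating type). No NOx/SO₂ chemistry, no upstream (life-cycle) fuel
emissions, no dispersion modelling.

## Exposure and health

PM₂.₅ emissions become population-average exposure through an intake
fraction iF (inhaled mass / emitted mass), keyed by source archetype: a
high-stack plant has a far smaller iF than ground-level residential
combustion. Intake is summed over sources *before* the nonlinear risk step.

- ΔC = E · 10¹² · iF / (P · BR · 365.25) µg/m³ (E in t/a, BR in m³/d).
- RR = exp(ln(RR₁₀) · max(ΔC − C₀, 0)/10); a linear form
  RR = 1 + (RR₁₀−1)·ΔC/10 is provided for cross-checks. C₀ defaults to 0:
  the model attributes the marginal source, not total ambient PM.
- deaths = P · M · (RR−1)/RR (population attributable fraction),
- DALY = deaths × YLL. Only mortality is counted; the YLD component is zero
  by design. YLL per death is a single scalar (default 10 a); age-structured
  life tables are out of scope.

For the small ΔC this model produces (≲ 0.5 µg/m³) the chain is linear to
first order, deaths ≈ P·M·ln(RR₁₀)/10 · ΔC, which the tests verify to 1 %.

## Uncertainty and importance

Distributions (`point`, `normal`, `lognormal`, `uniform`, `triangular`, with
optional truncation by clipping) attach to selected cells of any input
table. One value is drawn per iteration per distribution and applied to all
matched cells (replace or multiply); the targeted table gains an `Iteration`
index and the join semantics propagate it everywhere. Inputs are sampled
independently — no correlation structure is imposed. Deterministic mode
substitutes each distribution's median (analytic per family; truncation
applied by clipping the median).

Climate and health outcomes are combined at nominal 15 €/t CO₂ and
50 000 €/DALY into a single cost. The monetized CO₂ term uses **fossil**
CO₂, the regulated quantity a city's climate target is written against.
Importance = absolute Spearman rank correlation (Kendall optional) between
each input's draws and the monetized total, per decision-option combination,
either on absolute outputs or on per-iteration increments relative to BAU
(which are identically zero at BAU itself — reported as a missing
correlation, as are all zero-variance cases). Results are summarised as
min–max ranges per variable across combinations. The default run size is
1000 iterations.

## Synthetic city presets

The presets are structural stand-ins for real municipal datasets, not
statistical emulators of them. They reproduce documented *shape* anchors:

- `kuopio_like`: cohorts 1920–2000 with a post-1950 construction boom,
  88 % district heating / 8 % oil / 4 % electric, initial 5.2 Mm² giving
  ≈ 775 GWh/a of heat, constant construction that doubles the stock by 2050.
  District plant mix 84 % peat / 12 % heavy oil / 4 % wood; the fuel policy
  moves it to 49/1/50 from 2020 (linear transition 2010→2020). Renovation
  policies: BAU 3 %/a mixed depths, Active 4.5 %/a, Efficient 3 %/a all
  deep. Renovation savings 30–100 kWh/m²/a by depth.
- `basel_like`: half district heat (waste/wood/gas plant), half gas and oil,
  +20 % stock by 2030, savings 15–60 kWh/m²/a, renovation 1 %/2 %/exhaustive.
- `kuopio_mc`: the same city at reduced resolution (six cohorts, one
  building type, two heating types, horizon 2030) so that 1000-iteration
  Monte-Carlo runs complete in seconds; used for the shipped importance
  analysis.
- `mini`: one stratum, one fuel, zero construction and renovation — its
  end-to-end output has a one-line closed form
  (`mini_city_closed_form`), used as an independent oracle: the pipeline
  matches it to < 10⁻⁹ relative error.

Values the underlying datasets do not publish — PM₂.₅ emission factors, oil
and gas CO₂ factors, intake fractions, baseline mortality, RR₁₀, YLL — are
**calibration choices, not measured city data**. They are set once to
literature-typical magnitudes that place outputs at the documented order of
magnitude (≈ 1.5 premature deaths/a from the district-heat plant, tens of
DALY/a citywide). Within that calibration, the wood PM₂.₅ factor is set
marginally below peat's (0.09 vs 0.10 kg/MWh; same fluidised-bed plant and
flue-gas cleaning, slightly lower ash), so the peat→wood switch reduces
PM₂.₅ slightly while cutting fossil CO₂ by ~43 % — large relabeling, small
air-quality gain, which is the policy's documented character. The
`Wood_CO2_lifecycle` distribution targets wood's *total* CO₂ factor only;
since the monetized outcome uses fossil CO₂, it acts as a built-in null
input for the importance analysis.

Consequently, passing tests demonstrate the *mechanics* — conservation,
scenario algebra, uncertainty propagation, ranking behaviour — and the
qualitative policy orderings, not the reproduction of any real city's
burden estimates, which would require the original municipal datasets and
their unpublished exposure-response settings.

## Numerical choices and problem sizes

- Years are integer calendar years; eras are decade bins labelled by start
  year; the time step is 1 year.
- Mix-share tolerance 10⁻⁶; depth-share tolerance 10⁻⁹; division by zero in
  table arithmetic is an error, not an inf.
- Ties/degenerate inputs: zero eligible area or a zero renovation rate is an
  exact no-op; zero-variance inputs yield missing (not zero) correlations.
- Fixed seeds make every stochastic path bit-reproducible; the CLI manifest
  records config hash, seed and library versions.
- Shipped analyses use the preset sizes above: the deterministic factorial
  runs the full `kuopio_like` city (41 years × 9 cohorts × 2 building types
  × 3 heating types × 4 states × 6 scenarios), and the importance analysis
  uses `kuopio_mc` at 1000 iterations.

## Known limitations

Indoor air quality and thermal-comfort effects of renovation are outside the
model, as are life-cycle emissions of wood fuels (only flagged via the
sensitivity input), electricity-market compensation effects, spatial
(postal-code) disaggregation beyond carrying an optional area index, and
morbidity endpoints. The intake-fraction approach assumes a fixed
source-to-population relationship and cannot resolve within-city exposure
gradients.
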