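"""Synthetic city bundles for development, testing and demonstration.

The shipped presets emulate the *shape* of real city building-stock data --
a Finnish district-heat-dominated city ("kuopio_like": cohorts from 1920,
88 % district heating, ~800 GWh/a heat demand, stock doubling by 2050, a
peat-to-wood fuel policy and three renovation policies) and a Swiss city
("basel_like": half district heat, half gas and oil, >20 % stock growth by
2030) -- plus a one-stratum "mini" city whose end-to-end output has a
one-line closed form, used as an oracle.

Numbers the source datasets do not publish (PM2.5 emission factors, oil and
gas CO2 factors, intake fractions, baseline mortality, the exposure-response
slope) are calibration choices documented in the methods note: they place
the outputs at a realistic order of magnitude (roughly 1.5 premature
deaths/a from the district-heat plant, tens of DALY/a citywide) and are not
measured city data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .health import HealthParameters, DAYS_PER_YEAR, UG_PER_TONNE
from .pipeline import CityInputs
from .stock import RENOVATION_DEPTHS, era_of
from .tables import VALUE, DecisionTable, IndexedTable, TableError
from .uncertainty import InputDistribution, MonetizationWeights

PRESETS = ("mini", "kuopio_like", "kuopio_mc", "basel_like")


@dataclass
class CityTemplate:
    """Declarative description of a synthetic city.

    Shares are fractions in [0, 1]; eras are decade start years; demand
    levels are kWh/m²/a by era; the construction trajectory is m²/a.  Every
    stratum referenced anywhere must be covered by the demand and fuel
    tables, which :func:`generate_city` verifies before building anything.
    """

    name: str
    start: int
    end: int
    eras: list[int]
    building_types: list[str]
    building_shares: list[float]
    heating_types: list[str]
    heating_shares: list[float]
    initial_area: float                       # m² in the start year
    construction_per_year: float              # m²/a, constant trajectory
    demand_by_era: dict[int, float]           # kWh/m²/a, unrenovated
    new_build_demand: float                   # kWh/m²/a for post-start eras
    savings: dict[str, float]                 # kWh/m²/a per renovation depth
    era_weights: list[float]                  # relative cohort sizes
    fuel_mix: list[tuple]                     # (Heating, Fuel, Time, share)
    efficiency: dict[str, float]              # MWh fuel per MWh heat
    emission_factors: list[tuple]             # (Fuel, Pollutant, kg/MWh)
    health: HealthParameters | None = None
    intake_by_heating: dict[str, float] = field(default_factory=dict)
    renovation_rate: float = 0.03
    depth_shares: dict[str, float] = field(
        default_factory=lambda: {"total_sheath": 1.0})
    age_threshold: int = 30
    seed: int = 0

    def validate(self) -> None:
        for label, shares in (("building", self.building_shares),
                              ("heating", self.heating_shares)):
            if abs(sum(shares) - 1.0) > 1e-9 or any(s < 0 for s in shares):
                raise TableError(f"{self.name}: invalid {label} shares")
        if len(self.building_shares) != len(self.building_types):
            raise TableError(f"{self.name}: building shares/types mismatch")
        if len(self.heating_shares) != len(self.heating_types):
            raise TableError(f"{self.name}: heating shares/types mismatch")
        if len(self.era_weights) != len(self.eras):
            raise TableError(f"{self.name}: era weights/eras mismatch")
        if self.end < self.start:
            raise TableError(f"{self.name}: horizon end before start")
        missing = [e for e in self.eras if e not in self.demand_by_era]
        if missing:
            raise TableError(f"{self.name}: no demand level for eras {missing}")
        missing_d = [d for d in RENOVATION_DEPTHS if d not in self.savings]
        if missing_d:
            raise TableError(f"{self.name}: no savings for depths {missing_d}")
        mixed = {h for h, _, _, _ in self.fuel_mix}
        uncovered = set(self.heating_types) - mixed
        if uncovered:
            raise TableError(f"{self.name}: no fuel mix for {sorted(uncovered)}")
        fuels = {f for _, f, _, _ in self.fuel_mix}
        factored = {f for f, _, _ in self.emission_factors}
        if fuels - factored:
            raise TableError(
                f"{self.name}: no emission factors for fuels {sorted(fuels - factored)}")
        if set(self.intake_by_heating) and \
                set(self.heating_types) - set(self.intake_by_heating):
            raise TableError(f"{self.name}: intake fractions do not cover heating types")
        if self.health is None:
            raise TableError(f"{self.name}: health parameters missing")


@dataclass
class CityBundle:
    """A generated input bundle plus its policies and uncertain inputs."""

    inputs: CityInputs
    decisions: DecisionTable
    distributions: list[InputDistribution]
    weights: MonetizationWeights
    template: CityTemplate


def generate_city(template: CityTemplate) -> CityBundle:
    """Build a full, validated input bundle from a template.

    The bundle is accepted by :func:`heatburden.pipeline.run_model` without
    edits; an inconsistent template raises before anything is built.  The
    same template (including its seed) always produces an identical bundle.
    """
    t = template
    t.validate()
    hp = t.health

    weights = np.asarray(t.era_weights, dtype=float)
    weights = weights / weights.sum()
    rows = []
    for era, w_era in zip(t.eras, weights):
        for btype, w_b in zip(t.building_types, t.building_shares):
            for htype, w_h in zip(t.heating_types, t.heating_shares):
                rows.append({"Time": t.start, "Built": era, "Building": btype,
                             "Heating": htype, "Renovation": "none",
                             VALUE: t.initial_area * w_era * w_b * w_h})
    initial = IndexedTable(pd.DataFrame(rows), "m2", "initial_stock")

    construction = None
    if t.construction_per_year > 0:
        crows = []
        for year in range(t.start + 1, t.end + 1):
            for btype, w_b in zip(t.building_types, t.building_shares):
                for htype, w_h in zip(t.heating_types, t.heating_shares):
                    crows.append({"Time": year, "Building": btype,
                                  "Heating": htype,
                                  VALUE: t.construction_per_year * w_b * w_h})
        construction = IndexedTable(pd.DataFrame(crows), "m2/a", "construction")

    demand_levels = dict(t.demand_by_era)
    for era in range(era_of(t.start), era_of(t.end) + 10, 10):
        demand_levels.setdefault(era, t.new_build_demand)
    demand_base = IndexedTable.from_records(
        [{"Built": e, VALUE: v} for e, v in sorted(demand_levels.items())],
        unit="kWh/m2/a", name="demand_base")
    savings = IndexedTable.from_records(
        [{"Renovation": k, VALUE: v} for k, v in t.savings.items()],
        unit="kWh/m2/a", name="renovation_savings")

    mix = IndexedTable.from_records(
        [{"Heating": h, "Fuel": f, "Time": y, VALUE: s}
         for h, f, y, s in t.fuel_mix],
        unit="share", name="fuel_mix")
    eff = IndexedTable.from_records(
        [{"Heating": h, VALUE: v} for h, v in t.efficiency.items()],
        unit="1", name="efficiency")
    factors = IndexedTable.from_records(
        [{"Fuel": f, "Pollutant": p, VALUE: v}
         for f, p, v in t.emission_factors],
        unit="kg/MWh", name="emission_factors")

    if t.intake_by_heating:
        intake = IndexedTable.from_records(
            [{"Heating": h, VALUE: v} for h, v in t.intake_by_heating.items()],
            unit="1", name="intake_fraction")
    else:
        intake = IndexedTable.scalar(hp.intake_fraction, "1", "intake_fraction")

    tables = {
        "initial_stock": initial,
        "renovation_rate": IndexedTable.scalar(t.renovation_rate, "1/a",
                                               "renovation_rate"),
        "depth_shares": IndexedTable.from_records(
            [{"Renovation": k, VALUE: v} for k, v in t.depth_shares.items()],
            unit="share", name="depth_shares"),
        "demand_base": demand_base,
        "renovation_savings": savings,
        "fuel_mix": mix,
        "efficiency": eff,
        "emission_factors": factors,
        "population": IndexedTable.scalar(hp.population, "persons", "population"),
        "background_mortality": IndexedTable.scalar(
            hp.background_mortality, "1/a", "background_mortality"),
        "breathing_rate": IndexedTable.scalar(hp.breathing_rate, "m3/d",
                                              "breathing_rate"),
        "intake_fraction": intake,
        "rr_per_10": IndexedTable.scalar(hp.rr_per_10, "1", "rr_per_10"),
        "yll_per_death": IndexedTable.scalar(hp.yll_per_death, "a",
                                             "yll_per_death"),
    }
    if construction is not None:
        tables["construction"] = construction

    inputs = CityInputs(tables=tables, horizon=(t.start, t.end),
                        age_threshold=t.age_threshold,
                        erf_form=hp.erf_form,
                        counterfactual=hp.counterfactual,
                        name=t.name)
    decisions, dists = _policies_for(t)
    return CityBundle(inputs=inputs, decisions=decisions, distributions=dists,
                      weights=MonetizationWeights(), template=t)


def _decision_rows(rows):
    return DecisionTable(pd.DataFrame(
        rows, columns=["Decision", "Option", "Target", "Selector", "Change", "Value"]))


def _policies_for(t: CityTemplate) -> tuple[DecisionTable, list[InputDistribution]]:
    if t.name.startswith("kuopio"):
        return _kuopio_policies(t)
    if t.name.startswith("basel"):
        return _basel_policies(t)
    return _decision_rows([]), []


# ---------------------------------------------------------------- presets
def mini_template() -> CityTemplate:
    """One stratum, one fuel, constant stock: the closed-form oracle city."""
    return CityTemplate(
        name="mini", start=2010, end=2020,
        eras=[1990], era_weights=[1.0],
        building_types=["block"], building_shares=[1.0],
        heating_types=["district"], heating_shares=[1.0],
        initial_area=1e6, construction_per_year=0.0,
        demand_by_era={1990: 150.0}, new_build_demand=150.0,
        savings={"windows": 30.0, "windows_sheath_tech": 65.0,
                 "total_sheath": 100.0},
        fuel_mix=[("district", "peat", 2010, 1.0)],
        efficiency={"district": 1.0},
        emission_factors=[("peat", "CO2_fossil", 380.0),
                          ("peat", "CO2_total", 380.0),
                          ("peat", "PM2.5", 0.1)],
        health=HealthParameters(
            population=100_000, background_mortality=0.01,
            breathing_rate=13.0, intake_fraction=1e-5,
            rr_per_10=1.062, yll_per_death=10.0),
        renovation_rate=0.0,
    )


_KUOPIO_HEALTH = HealthParameters(
    population=105_000, background_mortality=0.0095,
    breathing_rate=13.0, intake_fraction=1.5e-6,
    rr_per_10=1.062, yll_per_death=10.0)

# district heat comes from a high-stack cogeneration plant (low intake
# fraction); oil and electric heating sit at ground level in the city
_KUOPIO_IF = {"district": 1.5e-6, "oil": 1e-5, "electric": 1e-5}

_KUOPIO_MIX = [
    # BAU plant mix held constant: 84 % peat, 12 % heavy oil, 4 % wood biomass
    ("district", "peat", 2010, 0.84), ("district", "heavy_oil", 2010, 0.12),
    ("district", "wood", 2010, 0.04),
    ("district", "peat", 2020, 0.84), ("district", "heavy_oil", 2020, 0.12),
    ("district", "wood", 2020, 0.04),
    ("district", "peat", 2050, 0.84), ("district", "heavy_oil", 2050, 0.12),
    ("district", "wood", 2050, 0.04),
    ("oil", "heating_oil", 2010, 1.0), ("oil", "heating_oil", 2050, 1.0),
    ("electric", "electricity", 2010, 1.0), ("electric", "electricity", 2050, 1.0),
]

_KUOPIO_FACTORS = [
    ("peat", "CO2_fossil", 380.0), ("peat", "CO2_total", 380.0),
    ("peat", "PM2.5", 0.10),
    # same fluidised-bed plant and flue-gas cleaning for wood as for peat:
    # slightly lower ash than peat, so marginally lower PM per MWh
    ("wood", "CO2_fossil", 0.0), ("wood", "CO2_total", 420.0),
    ("wood", "PM2.5", 0.09),
    ("heavy_oil", "CO2_fossil", 267.0), ("heavy_oil", "CO2_total", 267.0),
    ("heavy_oil", "PM2.5", 0.08),
    ("heating_oil", "CO2_fossil", 267.0), ("heating_oil", "CO2_total", 267.0),
    ("heating_oil", "PM2.5", 0.05),
    # grid electricity: no local combustion, no local emissions
    ("electricity", "CO2_fossil", 0.0), ("electricity", "CO2_total", 0.0),
    ("electricity", "PM2.5", 0.0),
]


def kuopio_like_template() -> CityTemplate:
    """District-heat-dominated northern city, cohorts 1920-2000, doubling stock."""
    eras = list(range(1920, 2010, 10))
    # small pre-war cohorts, construction boom from the 1960s on
    era_weights = [2, 2, 3, 6, 10, 12, 12, 13, 14]
    initial_area = 5.2e6
    return CityTemplate(
        name="kuopio_like", start=2010, end=2050,
        eras=eras, era_weights=[float(w) for w in era_weights],
        building_types=["apartment", "detached"],
        building_shares=[0.6, 0.4],
        heating_types=["district", "oil", "electric"],
        heating_shares=[0.88, 0.08, 0.04],
        initial_area=initial_area,
        construction_per_year=initial_area / 40.0,  # stock doubles by 2050
        demand_by_era={1920: 185.0, 1930: 180.0, 1940: 175.0, 1950: 170.0,
                       1960: 165.0, 1970: 155.0, 1980: 145.0, 1990: 135.0,
                       2000: 125.0},
        new_build_demand=80.0,
        savings={"windows": 30.0, "windows_sheath_tech": 65.0,
                 "total_sheath": 100.0},
        fuel_mix=list(_KUOPIO_MIX),
        efficiency={"district": 1.10, "oil": 1.15, "electric": 1.0},
        emission_factors=list(_KUOPIO_FACTORS),
        health=_KUOPIO_HEALTH,
        intake_by_heating=dict(_KUOPIO_IF),
        renovation_rate=0.03,
        depth_shares={"windows": 0.4, "windows_sheath_tech": 0.4,
                      "total_sheath": 0.2},
    )


def kuopio_mc_template() -> CityTemplate:
    """Reduced-resolution variant of the same city for Monte-Carlo runs.

    Fewer cohorts, two heating types and a 2030 horizon keep sample runs with
    ~1000 iterations fast while preserving the structure of the full preset.
    """
    t = kuopio_like_template()
    t.name = "kuopio_mc"
    t.end = 2030
    t.eras = list(range(1950, 2010, 10))
    t.era_weights = [10.0, 12.0, 12.0, 13.0, 14.0, 14.0]
    t.building_types = ["apartment"]
    t.building_shares = [1.0]
    t.heating_types = ["district", "oil"]
    t.heating_shares = [0.92, 0.08]
    t.demand_by_era = {e: t.demand_by_era[e] for e in t.eras}
    t.fuel_mix = [(h, f, y, s) for h, f, y, s in t.fuel_mix
                  if h in ("district", "oil")]
    t.efficiency = {"district": 1.10, "oil": 1.15}
    t.intake_by_heating = {"district": 1.5e-6, "oil": 1e-5}
    return t


_BASEL_HEALTH = HealthParameters(
    population=192_000, background_mortality=0.009,
    breathing_rate=13.0, intake_fraction=2e-6,
    rr_per_10=1.062, yll_per_death=10.0)

_BASEL_MIX = [
    # BAU district mix: 50 % waste, 10 % wood, 40 % gas
    ("district", "waste", 2010, 0.50), ("district", "wood", 2010, 0.10),
    ("district", "gas", 2010, 0.40),
    ("district", "waste", 2020, 0.50), ("district", "wood", 2020, 0.10),
    ("district", "gas", 2020, 0.40),
    ("district", "waste", 2050, 0.50), ("district", "wood", 2050, 0.10),
    ("district", "gas", 2050, 0.40),
    ("gas", "gas", 2010, 1.0), ("gas", "gas", 2050, 1.0),
    ("oil", "light_oil", 2010, 1.0), ("oil", "light_oil", 2050, 1.0),
]

_BASEL_FACTORS = [
    ("waste", "CO2_fossil", 150.0), ("waste", "CO2_total", 330.0),
    ("waste", "PM2.5", 0.06),
    ("wood", "CO2_fossil", 0.0), ("wood", "CO2_total", 420.0),
    ("wood", "PM2.5", 0.12),
    ("gas", "CO2_fossil", 202.0), ("gas", "CO2_total", 202.0),
    ("gas", "PM2.5", 0.01),
    ("light_oil", "CO2_fossil", 267.0), ("light_oil", "CO2_total", 267.0),
    ("light_oil", "PM2.5", 0.05),
]


def basel_like_template() -> CityTemplate:
    """Mid-European city: half district heat, half gas and oil, 20 % growth to 2030."""
    eras = list(range(1900, 2010, 10))
    era_weights = [4, 5, 6, 7, 8, 10, 12, 12, 12, 12, 12]
    initial_area = 8.0e6
    return CityTemplate(
        name="basel_like", start=2010, end=2050,
        eras=eras, era_weights=[float(w) for w in era_weights],
        building_types=["apartment", "row"],
        building_shares=[0.7, 0.3],
        heating_types=["district", "gas", "oil"],
        heating_shares=[0.50, 0.27, 0.23],
        initial_area=initial_area,
        construction_per_year=initial_area * 0.20 / 20.0,  # +20 % by 2030
        demand_by_era={1900: 140.0, 1910: 138.0, 1920: 135.0, 1930: 132.0,
                       1940: 130.0, 1950: 128.0, 1960: 125.0, 1970: 118.0,
                       1980: 110.0, 1990: 100.0, 2000: 90.0},
        new_build_demand=60.0,
        savings={"windows": 15.0, "windows_sheath_tech": 37.5,
                 "total_sheath": 60.0},
        fuel_mix=list(_BASEL_MIX),
        efficiency={"district": 1.10, "gas": 1.05, "oil": 1.15},
        emission_factors=list(_BASEL_FACTORS),
        health=_BASEL_HEALTH,
        intake_by_heating={"district": 2e-6, "gas": 1e-5, "oil": 1e-5},
        renovation_rate=0.01,
        depth_shares={"windows": 0.4, "windows_sheath_tech": 0.4,
                      "total_sheath": 0.2},
    )


def _kuopio_policies(t: CityTemplate):
    dec = _decision_rows([
        ("Renovation_policy", "Active", "renovation_rate", {}, "replace", 0.045),
        ("Renovation_policy", "Efficient", "depth_shares",
         {"Renovation": ["windows"]}, "replace", 0.0),
        ("Renovation_policy", "Efficient", "depth_shares",
         {"Renovation": ["windows_sheath_tech"]}, "replace", 0.0),
        ("Renovation_policy", "Efficient", "depth_shares",
         {"Renovation": ["total_sheath"]}, "replace", 1.0),
        # fuel policy: from 2020 on, 49 % peat / 1 % heavy oil / 50 % wood
        ("Fuel_policy", "Biofuel", "fuel_mix",
         {"Heating": ["district"], "Fuel": ["peat"], "Time": [2020, 2050]},
         "replace", 0.49),
        ("Fuel_policy", "Biofuel", "fuel_mix",
         {"Heating": ["district"], "Fuel": ["heavy_oil"], "Time": [2020, 2050]},
         "replace", 0.01),
        ("Fuel_policy", "Biofuel", "fuel_mix",
         {"Heating": ["district"], "Fuel": ["wood"], "Time": [2020, 2050]},
         "replace", 0.50),
    ])
    dists = [
        InputDistribution("ERF_PM2.5", "rr_per_10", "normal",
                          (1.062, 0.03), lower=1.001, upper=1.2),
        InputDistribution("Construction_volume", "construction", "uniform",
                          (0.85, 1.15), change="multiply"),
        InputDistribution("PM2.5_emission_factors", "emission_factors",
                          "lognormal", (0.0, 0.15),
                          selector={"Pollutant": ["PM2.5"]}, change="multiply"),
        InputDistribution("Low_energy_demand", "demand_base", "normal",
                          (80.0, 8.0), selector={"Built": [2010, 2020, 2030,
                                                           2040, 2050]},
                          lower=30.0),
        # life-cycle CO2 of wood: affects total CO2 only, not the fossil
        # CO2 + DALY monetized outcome -> a null-effect reference input
        InputDistribution("Wood_CO2_lifecycle", "emission_factors", "uniform",
                          (0.7, 1.3),
                          selector={"Fuel": ["wood"], "Pollutant": ["CO2_total"]},
                          change="multiply"),
    ]
    return dec, dists


def _basel_policies(t: CityTemplate):
    dec = _decision_rows([
        ("Renovation_policy", "Active", "renovation_rate", {}, "replace", 0.02),
        # exhaust the eligible stock well before the horizon end
        ("Renovation_policy", "Total", "renovation_rate", {}, "replace", 0.10),
        ("Fuel_policy", "Wood_increase", "fuel_mix",
         {"Heating": ["district"], "Fuel": ["wood"], "Time": [2020, 2050]},
         "replace", 0.30),
        ("Fuel_policy", "Wood_increase", "fuel_mix",
         {"Heating": ["district"], "Fuel": ["gas"], "Time": [2020, 2050]},
         "replace", 0.20),
    ])
    dists = [
        InputDistribution("ERF_PM2.5", "rr_per_10", "normal",
                          (1.062, 0.03), lower=1.001, upper=1.2),
        InputDistribution("Construction_volume", "construction", "uniform",
                          (0.85, 1.15), change="multiply"),
    ]
    return dec, dists


def get_template(preset: str) -> CityTemplate:
    try:
        return {"mini": mini_template,
                "kuopio_like": kuopio_like_template,
                "kuopio_mc": kuopio_mc_template,
                "basel_like": basel_like_template}[preset]()
    except KeyError:
        raise TableError(f"unknown preset {preset!r}; choose from {PRESETS}")


# ------------------------------------------------------------------ oracle
def mini_city_closed_form(area: float, demand: float, pm_factor: float,
                          hp: HealthParameters, eff: float = 1.0,
                          co2_factor: float = 380.0) -> dict[str, float]:
    """Analytic end-to-end outputs for a one-stratum, one-fuel city.

    Written as straight-line arithmetic, independent of the table machinery,
    so it can serve as an oracle for the full pipeline:

    fuel MWh/a   = area · demand / 1000 · eff
    PM2.5 t/a    = fuel · pm_factor / 1000
    ΔC µg/m³     = PM2.5 · 1e12 · iF / (P · BR · 365.25)
    RR           = exp(ln(RR10) · ΔC / 10)
    deaths/a     = P · M · (RR − 1) / RR
    DALY/a       = deaths · YLL
    """
    fuel_mwh = area * demand / 1000.0 * eff
    pm = fuel_mwh * pm_factor / 1000.0
    co2 = fuel_mwh * co2_factor / 1000.0
    delta_c = (pm * UG_PER_TONNE * hp.intake_fraction
               / (hp.population * hp.breathing_rate * DAYS_PER_YEAR))
    rr = math.exp(math.log(hp.rr_per_10) * delta_c / 10.0)
    deaths = hp.population * hp.background_mortality * (rr - 1.0) / rr
    return {"fuel_mwh": fuel_mwh, "pm_t": pm, "co2_t": co2,
            "delta_c": delta_c, "rr": rr, "deaths": deaths,
            "daly": deaths * hp.yll_per_death}
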