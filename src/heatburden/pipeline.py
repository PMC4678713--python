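"""End-to-end model runs: stock → heat → fuel → emissions → burden.

The model chain is deterministic; scenarios and Monte-Carlo samples enter as
index columns on the input tables and flow through the index-aligned
arithmetic.  :func:`run_model` wires the modules together for a complete city
input bundle, in either deterministic-median or Monte-Carlo mode, and
optionally monetizes the CO2 and DALY outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import emissions as em
from . import energy, health, stock, uncertainty
from .tables import (
    IndexedTable,
    DecisionTable,
    TableError,
    apply_decisions,
)

#: table names a complete input bundle must provide
REQUIRED_TABLES = (
    "initial_stock", "renovation_rate", "depth_shares",
    "demand_base", "renovation_savings",
    "fuel_mix", "emission_factors",
    "population", "background_mortality", "breathing_rate",
    "intake_fraction", "rr_per_10", "yll_per_death",
)

OPTIONAL_TABLES = ("construction", "efficiency", "demolition")


@dataclass
class CityInputs:
    """A complete, internally consistent input bundle for one city.

    ``tables`` maps reserved names (see :data:`REQUIRED_TABLES`) to
    :class:`IndexedTable` values; health parameters are scalar tables so that
    decisions and distributions can target them like any other input.
    """

    tables: dict[str, IndexedTable]
    horizon: tuple[int, int]
    age_threshold: int = 30
    demand_floor: float = 20.0
    erf_form: str = "loglinear"
    counterfactual: float = 0.0
    name: str = "city"

    def __post_init__(self) -> None:
        missing = [t for t in REQUIRED_TABLES if t not in self.tables]
        if missing:
            raise TableError(f"{self.name}: input bundle lacks tables {missing}")
        if self.horizon[1] < self.horizon[0]:
            raise TableError("horizon end before start")

    def health_params(self) -> dict[str, IndexedTable]:
        return {n: self.tables[n] for n in health._PARAM_NAMES}


@dataclass
class ModelOutputs:
    """Everything one run produces, each with scenario/Iteration indices."""

    stock: IndexedTable
    heat: IndexedTable
    fuel: IndexedTable
    emissions: IndexedTable
    deaths: IndexedTable
    daly: IndexedTable
    monetized: IndexedTable | None = None
    draws: pd.DataFrame | None = None

    def as_dict(self) -> dict[str, IndexedTable]:
        out = {"stock": self.stock, "heat": self.heat, "fuel": self.fuel,
               "emissions": self.emissions, "deaths": self.deaths,
               "daly": self.daly}
        if self.monetized is not None:
            out["monetized"] = self.monetized
        return out


def run_model(
    inputs: CityInputs,
    decisions: DecisionTable | None = None,
    mode: str = "deterministic",
    distributions: list[uncertainty.InputDistribution] | None = None,
    n_iter: int = 1000,
    seed: int | None = None,
    weights: uncertainty.MonetizationWeights | None = None,
) -> ModelOutputs:
    """Run the full chain for one city.

    In ``deterministic`` mode every distribution is replaced by its median
    and the model runs once; in ``monte_carlo`` mode the targeted tables gain
    an ``Iteration`` index of size ``n_iter`` (a seed is then mandatory) and
    every output is a sample.  Policies in ``decisions`` are expanded into
    scenario index columns; the BAU level always reproduces the no-policy
    run.
    """
    if mode not in ("deterministic", "monte_carlo"):
        raise TableError(f"unknown mode {mode!r}")
    tables = dict(inputs.tables)
    draws = None
    if distributions:
        if mode == "monte_carlo":
            if seed is None:
                raise TableError("monte_carlo mode requires a seed")
            tables, draws = uncertainty.sample_inputs(
                tables, distributions, n_iter, seed)
        else:
            tables = uncertainty.apply_medians(tables, distributions)

    tables = apply_decisions(tables, decisions)

    stk = stock.evolve_stock(
        tables["initial_stock"],
        tables.get("construction"),
        tables["renovation_rate"],
        tables["depth_shares"],
        horizon=inputs.horizon,
        age_threshold=inputs.age_threshold,
        demolition=tables.get("demolition"),
    )

    spec = energy.DemandSpec(
        base=tables["demand_base"],
        savings=tables["renovation_savings"],
        floor=inputs.demand_floor,
    )
    heat = energy.heat_demand(stk, spec)

    years = list(range(inputs.horizon[0], inputs.horizon[1] + 1))
    mix = em.interpolate_mix(tables["fuel_mix"], years)
    eff = tables.get("efficiency", 1.0)
    fuel = em.fuel_use(heat, mix, eff)
    emis = em.emissions_from_fuel(fuel, tables["emission_factors"])

    pm = emis.select(Pollutant="PM2.5")
    pm_keep = [c for c in ("Time", "Heating") if c in pm.index_cols]
    pm = pm.aggregate(pm_keep)
    params = {n: tables[n] for n in health._PARAM_NAMES}
    deaths, daly = health.burden_from_emissions(
        pm, params, erf_form=inputs.erf_form,
        counterfactual=inputs.counterfactual)

    monetized = None
    if weights is not None:
        co2 = emis.select(Pollutant="CO2_fossil").aggregate(["Time"])
        monetized = uncertainty.monetize(co2, daly, weights)

    return ModelOutputs(stock=stk, heat=heat, fuel=fuel, emissions=emis,
                        deaths=deaths, daly=daly, monetized=monetized,
                        draws=draws)
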