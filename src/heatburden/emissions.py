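"""Fuel use and emissions of the heating system.

Delivered heat (GWh/a by heating type) becomes fuel input (MWh/a) through a
conversion efficiency and a plant fuel mix, and fuel input becomes annual
emissions (t/a) of CO2_fossil, CO2_total and PM2.5 through per-fuel emission
factors (kg/MWh).  The fossil/total split matters because regulated "official"
CO2 counts peat as fossil while wood counts as zero despite its real stack
emissions.  All combustion emissions of a district-heat plant are attributed
to the delivered heat; electricity bought from outside the city is out of the
system boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import VALUE, IndexedTable, TableError, align_binary

POLLUTANTS = ("CO2_fossil", "CO2_total", "PM2.5")

MIX_TOL = 1e-9


def validate_mix(mix: IndexedTable) -> None:
    """Fuel shares must sum to 1 within each (Heating, Time, scenario, ...) group."""
    if "Fuel" not in mix.index_cols:
        raise TableError("fuel mix must be indexed by Fuel")
    group = [c for c in mix.index_cols if c != "Fuel"]
    if group:
        sums = mix.data.groupby(group)[VALUE].sum()
    else:
        sums = pd.Series([mix.data[VALUE].sum()])
    bad = sums[(sums - 1.0).abs() > 1e-6]
    if len(bad):
        raise TableError(f"fuel shares do not sum to 1: {bad.head().to_dict()}")
    if (mix.values < -MIX_TOL).any() or (mix.values > 1 + 1e-6).any():
        raise TableError("fuel shares outside [0, 1]")


def validate_factors(factors: IndexedTable) -> None:
    if not {"Fuel", "Pollutant"} <= set(factors.index_cols):
        raise TableError("emission factors must be indexed by Fuel and Pollutant")
    if (factors.values < 0).any():
        raise TableError("negative emission factor")
    df = factors.data
    wide = df.pivot_table(index=[c for c in factors.index_cols if c != "Pollutant"],
                          columns="Pollutant", values=VALUE)
    if {"CO2_fossil", "CO2_total"} <= set(wide.columns):
        bad = wide[wide["CO2_fossil"] > wide["CO2_total"] + 1e-9]
        if len(bad):
            raise TableError(
                f"CO2_fossil exceeds CO2_total for {bad.index.tolist()}")


def interpolate_mix(mix: IndexedTable, years: list[int]) -> IndexedTable:
    """Linearly interpolate fuel-mix anchor years onto every model year.

    A mix without a Time column is time-constant and returned as-is.  Outside
    the anchor range the nearest anchor is held constant.
    """
    if "Time" not in mix.index_cols:
        return mix
    keys = [c for c in mix.index_cols if c != "Time"]
    out = []
    for key, grp in mix.data.groupby(keys, sort=False):
        grp = grp.sort_values("Time")
        anchors = grp["Time"].astype(float).to_numpy()
        vals = grp[VALUE].to_numpy()
        interp = np.interp(np.asarray(years, dtype=float), anchors, vals)
        frame = pd.DataFrame({"Time": years, VALUE: interp})
        if not isinstance(key, tuple):
            key = (key,)
        for c, v in zip(keys, key):
            frame[c] = v
        out.append(frame[keys + ["Time", VALUE]])
    df = pd.concat(out, ignore_index=True)
    return IndexedTable(df, mix.unit, mix.name, mix.decisions)


def fuel_use(heat: IndexedTable, mix: IndexedTable,
             eff: IndexedTable | float = 1.0) -> IndexedTable:
    """Fuel input, MWh/a, by (Time, Heating, Fuel [, scenario, Iteration]).

    ``eff`` is MWh fuel input per MWh heat delivered (per heating type or a
    global scalar); ``mix`` gives fuel shares per heating type.
    """
    validate_mix(mix)
    if not isinstance(eff, IndexedTable):
        eff = IndexedTable.scalar(float(eff), "1", "efficiency")
    if (eff.values <= 0).any():
        raise TableError("conversion efficiency must be positive")
    if "Heating" in heat.index_cols and "Heating" in mix.index_cols:
        missing = set(heat.data["Heating"]) - set(mix.data["Heating"])
        if missing:
            raise TableError(f"fuel mix does not cover heating types {sorted(missing)}")
    mwh = heat.transform(lambda v: v * 1000.0)
    fuel = align_binary(align_binary(mwh, eff, "*"), mix, "*")
    return IndexedTable(fuel.data, "MWh/a", "fuel_use", fuel.decisions)


def emissions_from_fuel(fuel: IndexedTable, factors: IndexedTable) -> IndexedTable:
    """Emissions, t/a, by (Time, ..., Fuel, Pollutant) = MWh × kg/MWh / 1000."""
    validate_factors(factors)
    if "Fuel" in fuel.index_cols:
        missing = set(fuel.data["Fuel"]) - set(factors.data["Fuel"])
        if missing:
            raise TableError(f"no emission factors for fuels {sorted(missing)}")
    em = align_binary(fuel, factors, "*").transform(lambda v: v / 1000.0)
    return IndexedTable(em.data, "t/a", "emissions", em.decisions)


def fuel_policy_delta(mix_bau: IndexedTable, mix_policy: IndexedTable,
                      heat: IndexedTable, factors: IndexedTable,
                      eff: IndexedTable | float = 1.0) -> IndexedTable:
    """Per-pollutant emission difference of a fuel-mix policy versus BAU.

    Both mixes are run through the same heat demand and factors; the result
    (policy − BAU) is aggregated over Fuel, so it is the net change per
    pollutant and year.
    """
    keep = [c for c in ("Time", "Pollutant") if True]
    e_b = emissions_from_fuel(fuel_use(heat, mix_bau, eff), factors)
    e_p = emissions_from_fuel(fuel_use(heat, mix_policy, eff), factors)
    keep_b = [c for c in keep if c in e_b.index_cols]
    delta = align_binary(e_p.aggregate(keep_b),
                         e_b.aggregate(keep_b).transform(lambda v: -v), "+")
    return IndexedTable(delta.data, "t/a", "emission_delta", delta.decisions)
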