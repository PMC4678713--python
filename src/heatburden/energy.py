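"""Heating-energy demand of the building stock.

Floor area is converted to annual heating-energy demand with a specific
demand (kWh/m²/a) that depends on building type and construction era, and is
reduced by renovation according to per-depth savings.  Only heating energy is
modelled; electricity for other uses is out of the system boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import VALUE, IndexedTable, TableError, align_binary

from .stock import RENOVATION_DEPTHS


@dataclass
class DemandSpec:
    """Specific heating demand and renovation savings.

    ``base`` is the unrenovated specific demand (kWh/m²/a) indexed by any
    subset of {Building, Built}; ``savings`` (kWh/m²/a) is indexed by
    Renovation depth.  Post-renovation demand is floored at ``floor`` so deep
    renovation of an already-efficient cohort cannot go negative.  ``climate``
    is an optional global scalar on demand (e.g. for degree-day adjustment).
    """

    base: IndexedTable
    savings: IndexedTable
    floor: float | None = 20.0
    climate: float = 1.0

    def __post_init__(self) -> None:
        if (self.base.values <= 0).any():
            raise TableError("specific demand must be positive")
        if (self.savings.values < 0).any():
            raise TableError("renovation savings must be non-negative")
        if "Renovation" not in self.savings.index_cols:
            raise TableError("savings table must be indexed by Renovation")


def post_renovation_demand(spec: DemandSpec) -> IndexedTable:
    """Specific demand by renovation state: base minus per-depth saving.

    Returns a table indexed by the base indices plus ``Renovation`` covering
    the unrenovated state (saving 0) and every depth in the savings table.
    """
    sav = spec.savings.data
    states = list(sav["Renovation"].unique())
    missing = [d for d in RENOVATION_DEPTHS if d not in states]
    if missing:
        raise TableError(f"savings table lacks renovation depths {missing}")
    if "none" not in states:
        sav = pd.concat(
            [sav, pd.DataFrame([{**{c: "none" for c in ["Renovation"]}, VALUE: 0.0}])],
            ignore_index=True)
    sav_t = IndexedTable(sav, spec.savings.unit, "savings", spec.savings.decisions)
    demand = align_binary(spec.base, sav_t.transform(lambda v: -v), "+")
    vals = demand.values * spec.climate
    if spec.floor is None:
        if (vals <= 0).any():
            raise TableError("negative post-renovation demand (no floor configured)")
    else:
        vals = np.maximum(vals, spec.floor)
    df = demand.data.copy()
    df[VALUE] = vals
    return IndexedTable(df, spec.base.unit, "specific_demand", demand.decisions)


def _check_coverage(stock: IndexedTable, spec_table: IndexedTable) -> None:
    keys = [c for c in spec_table.index_cols
            if c in stock.index_cols]
    if not keys:
        return
    have = spec_table.data[keys].drop_duplicates()
    probe = stock.data[keys].drop_duplicates().merge(
        have.assign(__ok=1), on=keys, how="left")
    missing = probe[probe["__ok"].isna()]
    if len(missing):
        rows = missing[keys].head(10).to_dict("records")
        raise TableError(f"demand spec does not cover stock strata: {rows}")


def heat_demand(stock: IndexedTable, demand: IndexedTable | DemandSpec,
                keep: tuple[str, ...] = ("Time", "Heating")) -> IndexedTable:
    """Annual heating-energy demand, GWh/a, aggregated to ``keep``.

    ``demand`` is either the output of :func:`post_renovation_demand` or a
    :class:`DemandSpec` (expanded internally).  Every stock stratum must be
    covered by the demand table.  Decision and Iteration columns on either
    operand propagate to the output.
    """
    if isinstance(demand, DemandSpec):
        demand = post_renovation_demand(demand)
    _check_coverage(stock, demand)
    kwh = align_binary(stock, demand, "*")
    keep_present = [c for c in keep if c in kwh.index_cols]
    gwh = kwh.aggregate(keep_present).transform(lambda v: v / 1e6)
    return IndexedTable(gwh.data, "GWh/a", "heat_demand", gwh.decisions)
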