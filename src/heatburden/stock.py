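"""Building-stock dynamics: cohorts, construction, and age-gated renovation.

The stock is floor area (m²) indexed by Time, Built (construction era, decade
start year), Building (type), Heating (system) and Renovation state.  Each
simulated year carries the previous year's rows forward, adds new
construction, and moves a policy-controlled fraction of the eligible
(unrenovated, over-age-threshold) area into renovated states.  Renovation
conserves total floor area; demolition is off by default but can be supplied
as a per-year fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import (
    ITERATION,
    VALUE,
    IndexedTable,
    TableError,
    align_binary,
)

RENOVATION_STATES = ("none", "windows", "windows_sheath_tech", "total_sheath")
#: renovated states ordered from shallowest to deepest
RENOVATION_DEPTHS = RENOVATION_STATES[1:]

STOCK_INDICES = ("Built", "Building", "Heating", "Renovation")

ERA_BIN = 10


def era_of(year: int, bin_width: int = ERA_BIN) -> int:
    """Decade bin (labelled by start year) a construction year falls into."""
    return int(year) // bin_width * bin_width


@dataclass
class RenovationPolicy:
    """Annual renovation of old, so-far-unrenovated floor area.

    ``rate`` is the fraction of eligible area renovated per year; a building
    cohort becomes eligible once its era start year is more than
    ``age_threshold`` years in the past.  ``depth_shares`` splits the renovated
    area between renovation depths and must sum to 1.
    """

    rate: float
    age_threshold: int = 30
    depth_shares: dict[str, float] = field(
        default_factory=lambda: {"total_sheath": 1.0})

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise TableError(f"renovation rate {self.rate} outside [0, 1]")
        unknown = set(self.depth_shares) - set(RENOVATION_DEPTHS)
        if unknown:
            raise TableError(f"unknown renovation depths {sorted(unknown)}")
        if abs(sum(self.depth_shares.values()) - 1.0) > 1e-9:
            raise TableError("depth shares must sum to 1")

    def rate_table(self) -> IndexedTable:
        return IndexedTable.scalar(self.rate, "1/a", "renovation_rate")

    def depth_table(self) -> IndexedTable:
        return IndexedTable.from_records(
            [{"Renovation": k, VALUE: v} for k, v in self.depth_shares.items()],
            unit="share", name="depth_shares")


def _check_stock(stock: IndexedTable) -> None:
    cols = stock.index_cols
    for c in ("Built", "Renovation"):
        if c not in cols:
            raise TableError(f"stock table lacks index column {c!r}")
    if (stock.values < 0).any():
        raise TableError("negative floor area in stock")


def eligible_area(stock_at_t: IndexedTable, t: int, age_threshold: int = 30) -> IndexedTable:
    """Floor area eligible for renovation at year ``t``.

    Eligible means still unrenovated and older than the age threshold,
    measured conservatively from the era *start* year.
    """
    _check_stock(stock_at_t)
    df = stock_at_t.data
    if "Time" in df.columns:
        times = df["Time"].unique()
        if len(times) > 1:
            raise TableError("eligible_area expects a single-year stock slice")
        df = df.drop(columns=["Time"])
    mask = (df["Renovation"] == "none") & (t - df["Built"].astype(int) > age_threshold)
    return IndexedTable(df.loc[mask], stock_at_t.unit, "eligible_area",
                        stock_at_t.decisions)


def _extra_combos(df: pd.DataFrame, base_cols: set[str]) -> pd.DataFrame | None:
    """Unique combinations of columns in ``df`` beyond ``base_cols`` (or None)."""
    extra = [c for c in df.columns if c != VALUE and c not in base_cols]
    if not extra:
        return None
    return df[extra].drop_duplicates().reset_index(drop=True)


def _broadcast(df: pd.DataFrame, combos: pd.DataFrame | None) -> pd.DataFrame:
    if combos is None or combos.empty:
        return df
    missing = [c for c in combos.columns if c not in df.columns]
    if not missing:
        return df
    return df.merge(combos[missing].drop_duplicates(), how="cross")


def renovation_step(
    stock_at_t: IndexedTable,
    policy: RenovationPolicy | None = None,
    *,
    rate: IndexedTable | float | None = None,
    depth_shares: IndexedTable | None = None,
    t: int | None = None,
    age_threshold: int | None = None,
    rate_base: str = "unrenovated",
) -> IndexedTable:
    """Move one year's worth of renovations through the stock.

    ``rate`` × eligible area leaves ``Renovation='none'`` and is distributed
    over renovated states according to the depth shares.  Total floor area is
    conserved exactly.  ``rate`` and ``depth_shares`` may carry decision or
    Iteration columns, which then propagate into the stock.
    """
    if policy is not None:
        rate = policy.rate_table() if rate is None else rate
        depth_shares = policy.depth_table() if depth_shares is None else depth_shares
        age_threshold = policy.age_threshold if age_threshold is None else age_threshold
    if rate is None or depth_shares is None:
        raise TableError("renovation_step needs a policy or rate + depth_shares")
    if not isinstance(rate, IndexedTable):
        rate = IndexedTable.scalar(float(rate), "1/a", "renovation_rate")
    if (rate.values < 0).any() or (rate.values > 1).any():
        raise TableError("renovation rate outside [0, 1]")
    shares = depth_shares.aggregate([]).values
    if np.any(np.abs(shares - 1.0) > 1e-9):
        raise TableError("depth shares must sum to 1 per scenario")
    if age_threshold is None:
        age_threshold = 30
    if t is None:
        if "Time" not in stock_at_t.index_cols:
            raise TableError("renovation_step needs t when stock has no Time column")
        t = int(stock_at_t.data["Time"].iloc[0])

    stock_cols = set(stock_at_t.index_cols)
    no_new_cols = (set(rate.index_cols) <= stock_cols | {"Time"}
                   and set(depth_shares.index_cols) <= stock_cols | {"Renovation"})
    elig = eligible_area(stock_at_t, t, age_threshold)
    if len(elig) == 0 or ((rate.values == 0).all() and no_new_cols):
        return stock_at_t
    df = stock_at_t.data
    if "Time" in df.columns:
        df = df.drop(columns=["Time"])
    emask = (df["Renovation"] == "none") & (t - df["Built"].astype(int) > age_threshold)
    rest = IndexedTable(df.loc[~emask], stock_at_t.unit, stock_at_t.name,
                        stock_at_t.decisions)

    if rate_base == "all_over_threshold":
        # rate applies to all over-threshold area (renovated or not), but the
        # moved area still comes from -- and is capped by -- the unrenovated pool
        old = df.loc[t - df["Built"].astype(int) > age_threshold]
        strata = [c for c in old.columns if c not in (VALUE, "Renovation")]
        base = old.groupby(strata, as_index=False)[VALUE].sum()
        ratio = elig.data.merge(base, on=strata, suffixes=("", "_base"))
        ratio[VALUE] = ratio[f"{VALUE}_base"] / ratio[VALUE]
        ratio = IndexedTable(ratio.drop(columns=[f"{VALUE}_base"]), "1",
                             "pool_ratio", elig.decisions)
        eff_rate = align_binary(rate, ratio, "*").transform(
            lambda v: np.minimum(v, 1.0))
    elif rate_base == "unrenovated":
        eff_rate = rate
    else:
        raise TableError(f"unknown rate_base {rate_base!r}")

    moved = align_binary(elig, eff_rate, "*")
    stay = align_binary(elig, eff_rate.transform(lambda v: 1.0 - v), "*")
    moved_nr = IndexedTable(
        moved.data.drop(columns=["Renovation"]), moved.unit, moved.name,
        moved.decisions)
    renovated = align_binary(moved_nr, depth_shares, "*").with_unit(stock_at_t.unit)

    combos = _extra_combos(renovated.data,
                           set(rest.index_cols) | {"Renovation"})
    rest_df = _broadcast(rest.data, combos)
    stay_df = stay.data

    frames = [rest_df, stay_df, renovated.data]
    allcols = list(dict.fromkeys(c for f in frames for c in f.columns if c != VALUE))
    out = pd.concat([f.reindex(columns=allcols + [VALUE]) for f in frames],
                    ignore_index=True)
    out = out.groupby(allcols, as_index=False, sort=False)[VALUE].sum()
    decs = tuple(dict.fromkeys(stock_at_t.decisions + rate.decisions
                               + depth_shares.decisions))
    return IndexedTable(out, stock_at_t.unit, stock_at_t.name, decs)


def evolve_stock(
    initial: IndexedTable,
    plan: IndexedTable | None,
    rate: IndexedTable | float,
    depth_shares: IndexedTable | None = None,
    *,
    horizon: tuple[int, int],
    age_threshold: int = 30,
    demolition: IndexedTable | None = None,
    policy: RenovationPolicy | None = None,
) -> IndexedTable:
    """Evolve the stock year by year over ``horizon`` (inclusive).

    ``initial`` is the stock in the start year (with or without a Time
    column).  ``plan`` gives new floor area per year, building and heating
    type (``Renovation='none'``, Built = the current decade); a plan with
    missing years inside the horizon is an error.  Rate and depth tables may
    carry decision/Iteration columns; the whole stock is broadcast over those
    scenario combinations up front so every year's arithmetic aligns.
    """
    if policy is not None:
        rate = policy.rate_table()
        depth_shares = policy.depth_table()
        age_threshold = policy.age_threshold
    if not isinstance(rate, IndexedTable):
        rate = IndexedTable.scalar(float(rate), "1/a", "renovation_rate")
    if depth_shares is None:
        depth_shares = RenovationPolicy(0.0).depth_table()
    start, end = int(horizon[0]), int(horizon[1])
    if end < start:
        raise TableError("horizon end before start")
    _check_stock(initial)

    init = initial.data
    if "Time" in init.columns:
        t0 = int(init["Time"].max())
        if start < t0:
            raise TableError(f"horizon start {start} before initial stock year {t0}")
        init = init[init["Time"] == t0].drop(columns=["Time"])
    years = list(range(start, end + 1))

    plan_df = None
    if plan is not None and len(plan):
        plan_df = plan.data
        if "Time" not in plan_df.columns:
            raise TableError("construction plan needs a Time column")
        have = set(plan_df["Time"].astype(int))
        need = set(years[1:])
        gaps = sorted(need - have)
        if gaps:
            raise TableError(f"construction plan has gaps at years {gaps}")
        if (plan.values < 0).any():
            raise TableError("negative construction in plan")

    # broadcast initial stock over scenario/Iteration combos from inputs
    base_cols = set(init.columns)
    combo_frames = []
    for src in (rate.data, depth_shares.data,
                plan_df if plan_df is not None else pd.DataFrame(),
                demolition.data if demolition is not None else pd.DataFrame()):
        if len(src):
            cf = _extra_combos(src, base_cols | {"Time", "Renovation"})
            if cf is not None:
                combo_frames.append(cf)
    combos = None
    for cf in combo_frames:
        if combos is None:
            combos = cf
            continue
        shared = [c for c in cf.columns if c in combos.columns]
        if set(cf.columns) <= set(combos.columns):
            continue
        if shared:
            combos = combos.merge(cf, on=shared).drop_duplicates()
        else:
            combos = combos.merge(cf, how="cross").drop_duplicates()
    cur = _broadcast(init, combos)

    decs = tuple(dict.fromkeys(
        initial.decisions + rate.decisions + depth_shares.decisions
        + (plan.decisions if plan is not None else ())
        + (demolition.decisions if demolition is not None else ())))

    strata = [c for c in cur.columns if c != VALUE]
    snapshots = [cur.assign(Time=start)]
    for t in years[1:]:
        # new construction enters unrenovated in the current decade bin
        if plan_df is not None:
            new = plan_df[plan_df["Time"].astype(int) == t].drop(columns=["Time"])
            if len(new):
                new = new.assign(Built=era_of(t), Renovation="none")
                new = _broadcast(new, combos)
                new = new.reindex(columns=strata + [VALUE])
                if new[strata].isna().any().any():
                    missing = [c for c in strata if new[c].isna().any()]
                    raise TableError(f"construction plan lacks columns {missing}")
                cur = (pd.concat([cur, new], ignore_index=True)
                       .groupby(strata, as_index=False, sort=False)[VALUE].sum())
        if demolition is not None:
            dem = demolition.data
            row = dem[dem["Time"].astype(int) == t]
            if len(row):
                cur = cur.copy()
                cur[VALUE] *= 1.0 - float(row[VALUE].iloc[0])
        rate_t = rate
        if "Time" in rate.data.columns:
            rate_t = rate.select(Time=t)
        stepped = renovation_step(
            IndexedTable(cur, initial.unit, initial.name, decs),
            rate=rate_t, depth_shares=depth_shares, t=t,
            age_threshold=age_threshold)
        cur = stepped.data
        snapshots.append(cur.assign(Time=t))

    allcols = list(dict.fromkeys(c for f in snapshots for c in f.columns if c != VALUE))
    out = pd.concat([f.reindex(columns=allcols + [VALUE]) for f in snapshots],
                    ignore_index=True)
    out = out.fillna({c: 0.0 for c in [VALUE]})
    cols = ["Time"] + [c for c in allcols if c != "Time"]
    out = out[cols + [VALUE]]
    return IndexedTable(out, initial.unit, initial.name or "stock", decs)


def renovated_share(stock: IndexedTable, t: int, efficient_from: int = 2010) -> float:
    """Share of floor area at year ``t`` that is energy-efficient.

    Counts both renovated area (any depth) and area built in or after
    ``efficient_from``, which enters the stock at modern efficiency levels.
    """
    df = stock.data
    if "Time" in df.columns:
        df = df[df["Time"].astype(int) == int(t)]
    if not len(df) or df[VALUE].sum() <= 0:
        raise TableError(f"no floor area at Time={t}")
    good = (df["Renovation"] != "none") | (df["Built"].astype(int) >= efficient_from)
    return float(df.loc[good, VALUE].sum() / df[VALUE].sum())
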