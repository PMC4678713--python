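"""Monte-Carlo uncertainty propagation and rank-correlation importance.

Inputs may be declared uncertain with a distribution attached to selected
cells of an input table.  Sampling adds an ``Iteration`` index to the
targeted tables; the index-aligned arithmetic of the model then propagates it
through every downstream operation without further machinery.  A faster
deterministic mode replaces each distribution by its median.  Climate and
health outputs are combined into a monetized total (€/t CO2 and €/DALY), and
the importance of each uncertain input is the absolute rank correlation
between its draws and the monetized total, per decision-option combination,
either on absolute outputs or on increments relative to BAU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables import (
    BAU,
    ITERATION,
    VALUE,
    IndexedTable,
    TableError,
    _selector_mask,
    align_binary,
)

_FAMILIES = ("point", "normal", "lognormal", "uniform", "triangular")


@dataclass
class InputDistribution:
    """An uncertain input: a distribution attached to cells of one table.

    ``selector`` picks the targeted rows (empty = all rows); one value is
    drawn per iteration and applied to every matched cell, either replacing
    the cell (``change='replace'``) or scaling it (``change='multiply'``).
    ``lower``/``upper`` truncate the support by clipping.
    """

    name: str
    target: str
    dist: str
    params: tuple[float, ...]
    selector: dict[str, object] = field(default_factory=dict)
    change: str = "replace"
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.dist not in _FAMILIES:
            raise TableError(f"unknown distribution family {self.dist!r}")
        if self.change not in ("replace", "multiply"):
            raise TableError(f"unknown change type {self.change!r}")
        p = self.params = tuple(float(x) for x in self.params)
        if self.dist == "point" and len(p) != 1:
            raise TableError("point distribution takes one parameter")
        if self.dist in ("normal", "lognormal"):
            if len(p) != 2 or p[1] <= 0:
                raise TableError(f"{self.dist} needs (mu, sigma>0)")
        if self.dist == "uniform" and (len(p) != 2 or p[0] >= p[1]):
            raise TableError("uniform needs (a, b) with a < b")
        if self.dist == "triangular":
            if len(p) != 3 or not (p[0] <= p[1] <= p[2]) or p[0] >= p[2]:
                raise TableError("triangular needs (a, m, b) with a ≤ m ≤ b, a < b")
        if self.lower is not None and self.upper is not None \
                and self.lower >= self.upper:
            raise TableError("empty truncation interval")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self.params
        if self.dist == "point":
            draws = np.full(n, p[0])
        elif self.dist == "normal":
            draws = rng.normal(p[0], p[1], n)
        elif self.dist == "lognormal":
            draws = rng.lognormal(p[0], p[1], n)
        elif self.dist == "uniform":
            draws = rng.uniform(p[0], p[1], n)
        else:
            draws = rng.triangular(p[0], p[1], p[2], n)
        return self._clip(draws)

    def median(self) -> float:
        p = self.params
        if self.dist == "point":
            m = p[0]
        elif self.dist == "normal":
            m = p[0]
        elif self.dist == "lognormal":
            m = float(np.exp(p[0]))
        elif self.dist == "uniform":
            m = (p[0] + p[1]) / 2.0
        else:
            m = float(stats.triang.median(
                (p[1] - p[0]) / (p[2] - p[0]), loc=p[0], scale=p[2] - p[0]))
        return float(self._clip(np.asarray([m]))[0])

    def _clip(self, draws: np.ndarray) -> np.ndarray:
        lo = -np.inf if self.lower is None else self.lower
        hi = np.inf if self.upper is None else self.upper
        return np.clip(draws, lo, hi)


def _apply_to_table(table: IndexedTable, dist: InputDistribution,
                    values: pd.Series | float) -> IndexedTable:
    """Apply per-iteration (or scalar) values to the selected cells."""
    df = table.data.copy()
    mask = _selector_mask(df, dist.selector, table.name or dist.target)
    if not mask.any():
        raise TableError(
            f"distribution {dist.name!r}: selector matches no rows of "
            f"{dist.target!r}")
    if isinstance(values, pd.Series):
        mapped = df.loc[mask, ITERATION].map(values)
        if mapped.isna().any():
            raise TableError(f"distribution {dist.name!r}: unmapped iterations")
        vals = mapped.to_numpy()
    else:
        vals = values
    if dist.change == "multiply":
        df.loc[mask, VALUE] = df.loc[mask, VALUE] * vals
    else:
        df.loc[mask, VALUE] = vals
    return IndexedTable(df, table.unit, table.name, table.decisions)


def sample_inputs(
    tables: dict[str, IndexedTable],
    dists: list[InputDistribution],
    n_iter: int,
    seed: int,
) -> tuple[dict[str, IndexedTable], pd.DataFrame]:
    """Draw ``n_iter`` samples of every uncertain input.

    Every targeted table gains an ``Iteration`` index (integers 1..n) with
    one draw per distribution per iteration applied to the selected cells.
    Returns the updated tables and the draws (DataFrame indexed by Iteration,
    one column per distribution) for later importance analysis.  A fixed seed
    reproduces the draws bit for bit.
    """
    if n_iter < 1:
        raise TableError("n_iter must be ≥ 1")
    names = [d.name for d in dists]
    if len(set(names)) != len(names):
        raise TableError("distribution names must be unique")
    unknown = {d.target for d in dists} - set(tables)
    if unknown:
        raise TableError(f"distribution targets not in inputs: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    iters = pd.Index(np.arange(1, n_iter + 1), name=ITERATION)
    draws = pd.DataFrame(
        {d.name: d.sample(n_iter, rng) for d in dists}, index=iters)

    out = dict(tables)
    for d in dists:
        t = out[d.target]
        if ITERATION not in t.index_cols:
            df = t.data.merge(pd.DataFrame({ITERATION: iters}), how="cross")
            t = IndexedTable(df, t.unit, t.name, t.decisions)
        out[d.target] = _apply_to_table(t, d, draws[d.name])
    return out, draws


def apply_medians(
    tables: dict[str, IndexedTable],
    dists: list[InputDistribution],
) -> dict[str, IndexedTable]:
    """Deterministic mode: replace each distribution by its median."""
    out = dict(tables)
    for d in dists:
        out[d.target] = _apply_to_table(out[d.target], d, d.median())
    return out


@dataclass
class MonetizationWeights:
    """Nominal unit values combining climate and health impacts into €/a."""

    eur_per_t_co2: float = 15.0
    eur_per_daly: float = 50_000.0

    def __post_init__(self) -> None:
        if self.eur_per_t_co2 < 0 or self.eur_per_daly < 0:
            raise TableError("monetization weights must be non-negative")


def monetize(co2: IndexedTable, daly: IndexedTable,
             weights: MonetizationWeights | None = None) -> IndexedTable:
    """Monetized total cost, €/a: w_CO2 · CO2 + w_DALY · DALY.

    Both harms are positive costs; the monetized total is something a policy
    wants to push down.
    """
    w = weights or MonetizationWeights()
    a = co2.transform(lambda v: v * w.eur_per_t_co2, unit="EUR/a")
    b = daly.transform(lambda v: v * w.eur_per_daly, unit="EUR/a")
    out = align_binary(a, b, "+")
    return IndexedTable(out.data, "EUR/a", "monetized_total", out.decisions)


# ----------------------------------------------------------- importance
def _combination_label(cols: list[str], key) -> str:
    if not cols:
        return "-"
    if not isinstance(key, tuple):
        key = (key,)
    return ";".join(f"{c}={v}" for c, v in zip(cols, key))


def incremental_values(value: IndexedTable, bau: str = BAU) -> IndexedTable:
    """Per-iteration increment of a monetized output relative to BAU.

    The BAU combination itself yields identically zero increments.  The
    output must carry decision columns and the Iteration index.
    """
    dec_cols = [c for c in value.index_cols if c in value.decisions]
    if not dec_cols:
        raise TableError("incremental mode requires decision columns")
    if ITERATION not in value.index_cols:
        raise TableError("incremental mode requires the Iteration index")
    df = value.data
    bau_mask = np.logical_and.reduce([df[c] == bau for c in dec_cols])
    if not bau_mask.any():
        raise TableError("no BAU slice found in monetized output")
    ref = df.loc[bau_mask, [ITERATION, VALUE]].rename(columns={VALUE: "__bau"})
    merged = df.merge(ref, on=ITERATION, how="left")
    merged[VALUE] = merged[VALUE] - merged["__bau"]
    merged = merged.drop(columns="__bau")
    return IndexedTable(merged, value.unit, "incremental_" + (value.name or "value"),
                        value.decisions)


def importance(
    draws: pd.DataFrame,
    value: IndexedTable,
    mode: str = "absolute",
    method: str = "spearman",
    bau: str = BAU,
) -> pd.DataFrame:
    """Rank-correlation importance of each uncertain input.

    For every decision-option combination, the absolute Spearman (or Kendall)
    rank correlation between each input's draws and the monetized output,
    computed per iteration.  ``mode='incremental'`` first subtracts the BAU
    output of the same iteration.  Zero-variance inputs or outputs give a
    missing (NaN) correlation, not zero.

    Returns a DataFrame with columns Variable, Mode, Combination, AbsRankCorr.
    """
    if mode not in ("absolute", "incremental"):
        raise TableError(f"unknown importance mode {mode!r}")
    if method not in ("spearman", "kendall"):
        raise TableError(f"unknown correlation method {method!r}")
    if ITERATION not in value.index_cols:
        raise TableError("importance needs an Iteration index on the output")
    dec_cols = [c for c in value.index_cols if c in value.decisions]
    val = value.aggregate(dec_cols, how="sum")
    if mode == "incremental":
        val = incremental_values(val, bau=bau)
    df = val.data
    corr_fn = stats.spearmanr if method == "spearman" else stats.kendalltau

    groups = df.groupby(dec_cols, sort=False) if dec_cols else [(None, df)]
    records = []
    for key, grp in groups:
        label = _combination_label(dec_cols, key)
        series = grp.set_index(ITERATION)[VALUE]
        for var in draws.columns:
            x = draws[var].reindex(series.index).to_numpy()
            y = series.to_numpy()
            if np.unique(x).size <= 1 or np.unique(y).size <= 1:
                rho = np.nan
            else:
                rho = abs(float(corr_fn(x, y).statistic))
            records.append({"Variable": var, "Mode": mode,
                            "Combination": label, "AbsRankCorr": rho})
    return pd.DataFrame(records)


def importance_ranges(result: pd.DataFrame) -> pd.DataFrame:
    """Min-max range of |rank correlation| per variable and mode.

    This is the usual summary when a factorial of decision options produces
    several correlations per input variable.
    """
    return (result.groupby(["Variable", "Mode"], sort=False)["AbsRankCorr"]
            .agg(["min", "max"]).reset_index()
            .rename(columns={"min": "Low", "max": "High"}))
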