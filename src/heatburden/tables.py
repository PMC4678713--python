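"""Long-format indexed value tables and the policy/scenario engine.

Every quantity in the model (floor areas, specific demands, fuel shares,
emission factors, health parameters ...) is an :class:`IndexedTable`: a long
pandas DataFrame with named index columns, a single numeric ``Result`` column
and a unit string.  Arithmetic between tables is an inner join on the shared
index columns with broadcasting over the non-shared ones, which is what lets
extra dimensions -- a ``Iteration`` column with Monte-Carlo sample ids, or one
column per policy decision -- flow through the whole model without any change
to the model code.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALUE = "Result"
ITERATION = "Iteration"

_DIMENSIONLESS = {"", "1", "dimensionless", "fraction", "share", "-"}

log = logging.getLogger("heatburden")


class TableError(ValueError):
    """Invalid table content or an operation that cannot be carried out."""


class AlignmentError(TableError):
    """Two tables share an index column but have no overlapping values."""


@dataclass
class IndexedTable:
    """A long-format value table with named index columns and a unit.

    Parameters
    ----------
    data:
        DataFrame whose columns are the index columns (categorical strings or
        integer years) followed by the numeric ``Result`` column.
    unit:
        Free-text unit of the ``Result`` column (e.g. ``"m2"``, ``"GWh/a"``).
    name:
        Identifier used in error messages and when writing bundles.
    decisions:
        Names of index columns that are policy-decision (scenario) indices.
        These are created by :func:`apply_decisions` and are never silently
        dropped by aggregation.
    """

    data: pd.DataFrame
    unit: str
    name: str = ""
    decisions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TableError(f"{self.name or 'table'}: data must be a DataFrame")
        if VALUE not in self.data.columns:
            raise TableError(f"{self.name or 'table'}: missing '{VALUE}' column")
        if not isinstance(self.unit, str) or not self.unit:
            raise TableError(f"{self.name or 'table'}: unit must be a non-empty string")
        self.data = self.data.reset_index(drop=True)
        # value column numeric and finite
        vals = pd.to_numeric(self.data[VALUE], errors="coerce")
        if vals.isna().any() or not np.isfinite(vals.to_numpy(dtype=float)).all():
            bad = self.data.index[~np.isfinite(vals.to_numpy(dtype=float))].tolist()[:5]
            raise TableError(
                f"{self.name or 'table'}: non-numeric or non-finite Result in rows {bad}"
            )
        self.data[VALUE] = vals.astype(float)
        idx = self.index_cols
        if idx:
            dup = self.data.duplicated(subset=idx)
            if dup.any():
                first = self.data.loc[dup.idxmax(), idx].to_dict()
                raise TableError(
                    f"{self.name or 'table'}: duplicate index tuple {first}"
                )
        self.decisions = tuple(d for d in self.decisions if d in self.data.columns)

    # ------------------------------------------------------------------ basics
    @property
    def index_cols(self) -> list[str]:
        return [c for c in self.data.columns if c != VALUE]

    @property
    def values(self) -> np.ndarray:
        return self.data[VALUE].to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def scalar(cls, value: float, unit: str, name: str = "") -> "IndexedTable":
        """A zero-index table holding a single number (broadcasts over anything)."""
        return cls(pd.DataFrame({VALUE: [float(value)]}), unit=unit, name=name)

    @classmethod
    def from_records(
        cls,
        records: Iterable[Mapping[str, object]],
        unit: str,
        name: str = "",
        decisions: tuple[str, ...] = (),
    ) -> "IndexedTable":
        return cls(pd.DataFrame(list(records)), unit=unit, name=name, decisions=decisions)

    def copy(self) -> "IndexedTable":
        return IndexedTable(self.data.copy(), self.unit, self.name, self.decisions)

    def with_unit(self, unit: str) -> "IndexedTable":
        return IndexedTable(self.data.copy(), unit, self.name, self.decisions)

    def rename(self, name: str) -> "IndexedTable":
        return IndexedTable(self.data.copy(), self.unit, name, self.decisions)

    # -------------------------------------------------------------- selection
    def select(self, drop: bool = True, **criteria) -> "IndexedTable":
        """Filter rows by index-column values.

        Scalar criteria select one level and (by default) drop the column;
        list/set criteria keep the column.
        """
        df = self.data
        mask = pd.Series(True, index=df.index)
        to_drop: list[str] = []
        for col, val in criteria.items():
            if col not in df.columns:
                raise TableError(f"{self.name}: no index column {col!r}")
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= df[col].isin(list(val))
            else:
                mask &= df[col] == val
                if drop:
                    to_drop.append(col)
        out = df.loc[mask].drop(columns=to_drop)
        return IndexedTable(out, self.unit, self.name, self.decisions)

    def transform(self, func, unit: str | None = None) -> "IndexedTable":
        """Apply an elementwise function to the value column."""
        df = self.data.copy()
        df[VALUE] = func(df[VALUE].to_numpy())
        return IndexedTable(df, unit if unit is not None else self.unit, self.name, self.decisions)

    # ------------------------------------------------------------ aggregation
    def aggregate(
        self,
        keep: Sequence[str],
        how: str = "sum",
        drop_iteration: bool = False,
    ) -> "IndexedTable":
        """Sum or average over all index columns not in ``keep``.

        Decision (scenario) columns are always retained.  Dropping the
        ``Iteration`` column must be requested explicitly with
        ``drop_iteration=True``; otherwise it is retained as well.
        """
        keep = list(keep)
        missing = [c for c in keep if c not in self.index_cols]
        if missing:
            raise TableError(f"{self.name}: cannot keep absent columns {missing}")
        if how not in ("sum", "mean"):
            raise TableError(f"unknown aggregation {how!r}")
        protected = [c for c in self.index_cols if c in self.decisions]
        if ITERATION in self.index_cols:
            if drop_iteration:
                if ITERATION in keep:
                    raise TableError("drop_iteration=True contradicts keeping Iteration")
            else:
                protected.append(ITERATION)
        final = [c for c in self.index_cols if c in set(keep) | set(protected)]
        if not final:
            df = pd.DataFrame({VALUE: [self.data[VALUE].agg(how)]})
        else:
            df = self.data.groupby(final, as_index=False, sort=False)[VALUE].agg(how)
        return IndexedTable(df, self.unit, self.name, self.decisions)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        return align_binary(self, _as_table(other, self.unit), "+")

    def __sub__(self, other):
        return align_binary(self, _as_table(other, self.unit), "-")

    def __mul__(self, other):
        return align_binary(self, _as_table(other, "1"), "*")

    def __truediv__(self, other):
        return align_binary(self, _as_table(other, "1"), "/")


def _as_table(x, unit: str) -> IndexedTable:
    if isinstance(x, IndexedTable):
        return x
    return IndexedTable.scalar(float(x), unit)


def _combine_units(ua: str, ub: str, op: str) -> str:
    if op in "+-":
        if ua != ub:
            log.warning("unit mismatch in %s: %r vs %r (keeping first)", op, ua, ub)
        return ua
    a_dim = ua in _DIMENSIONLESS
    b_dim = ub in _DIMENSIONLESS
    if op == "*":
        if b_dim:
            return ua
        if a_dim:
            return ub
        return f"{ua}*{ub}"
    # division
    if ua == ub:
        return "1"
    if b_dim:
        return ua
    return f"{ua}/{ub}"


_OPS = {
    "+": np.add,
    "-": np.subtract,
    "*": np.multiply,
    "/": np.divide,
}


def align_binary(a: IndexedTable, b: IndexedTable, op: str) -> IndexedTable:
    """Index-aligned arithmetic between two tables.

    Rows are matched by an inner join on the shared index columns; index
    columns present in only one operand broadcast (every row of the other
    operand is combined with every matching level).  Rows whose shared-index
    values have no partner are dropped, with the count logged.
    """
    if op not in _OPS:
        raise TableError(f"unknown operator {op!r}")
    shared = [c for c in a.index_cols if c in b.index_cols]
    da = a.data.rename(columns={VALUE: "__a"})
    db = b.data.rename(columns={VALUE: "__b"})
    if shared:
        merged = da.merge(db, on=shared, how="inner")
        if merged.empty and len(da) and len(db):
            disjoint = [
                c for c in shared
                if not set(da[c].unique()) & set(db[c].unique())
            ]
            raise AlignmentError(
                f"no overlapping values on shared index "
                f"{disjoint or shared} between {a.name or 'a'} and {b.name or 'b'}"
            )
        lost_a = len(da) - da[shared].merge(merged[shared].drop_duplicates(), on=shared).shape[0]
        if lost_a:
            log.info("align %s%s%s: %d row(s) of %s dropped (unmatched index values)",
                     a.name or "a", op, b.name or "b", lost_a, a.name or "a")
    else:
        merged = da.merge(db, how="cross")
    if op == "/" and (merged["__b"] == 0).any():
        raise TableError(f"division by zero in {b.name or 'denominator'}")
    merged[VALUE] = _OPS[op](merged["__a"].to_numpy(), merged["__b"].to_numpy())
    merged = merged.drop(columns=["__a", "__b"])
    # stable column order: a's indices, then b-only indices
    order = a.index_cols + [c for c in b.index_cols if c not in a.index_cols]
    merged = merged[order + [VALUE]]
    return IndexedTable(
        merged,
        _combine_units(a.unit, b.unit, op),
        name=a.name or b.name,
        decisions=tuple(dict.fromkeys(a.decisions + b.decisions)),
    )


def aggregate(a: IndexedTable, keep: Sequence[str], how: str = "sum",
              drop_iteration: bool = False) -> IndexedTable:
    """Functional form of :meth:`IndexedTable.aggregate`."""
    return a.aggregate(keep, how=how, drop_iteration=drop_iteration)


# ---------------------------------------------------------------------------
# Policies as data: the scenario engine
# ---------------------------------------------------------------------------

BAU = "BAU"

_CHANGES = ("multiply", "add", "replace")


@dataclass
class DecisionTable:
    """Externally defined policies.

    One row per (decision, option, target-table) change.  Each decision turns
    into one new index column on every table it targets; the ``BAU`` option
    level always reproduces the untouched input.  Columns: ``Decision``,
    ``Option``, ``Target``, ``Selector`` (dict of index column -> allowed
    values), ``Change`` (multiply/add/replace) and ``Value``.
    """

    rows: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["Decision", "Option", "Target", "Selector", "Change", "Value"]))

    def __post_init__(self) -> None:
        required = ["Decision", "Option", "Target", "Selector", "Change", "Value"]
        missing = [c for c in required if c not in self.rows.columns]
        if missing:
            raise TableError(f"decision table missing columns {missing}")
        bad = set(self.rows["Change"]) - set(_CHANGES)
        if bad:
            raise TableError(f"unknown change type(s) {sorted(bad)}")
        if (self.rows["Option"] == BAU).any():
            raise TableError(f"option {BAU!r} is implicit and may not carry changes")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def decision_names(self) -> list[str]:
        return list(dict.fromkeys(self.rows["Decision"]))

    def options(self, decision: str) -> list[str]:
        opts = list(dict.fromkeys(
            self.rows.loc[self.rows["Decision"] == decision, "Option"]))
        return [BAU] + opts

    @staticmethod
    def encode_selector(sel: Mapping[str, object]) -> str:
        parts = []
        for col, vals in sel.items():
            if not isinstance(vals, (list, tuple, set, frozenset)):
                vals = [vals]
            parts.append(f"{col}=" + ",".join(str(v) for v in vals))
        return ";".join(parts)

    @staticmethod
    def decode_selector(text: str) -> dict[str, list[str]]:
        text = (text or "").strip()
        if not text:
            return {}
        out: dict[str, list[str]] = {}
        for part in text.split(";"):
            col, _, vals = part.partition("=")
            if not _:
                raise TableError(f"malformed selector fragment {part!r}")
            out[col.strip()] = [v.strip() for v in vals.split(",")]
        return out


def _selector_mask(df: pd.DataFrame, selector: Mapping[str, object],
                   table_name: str) -> pd.Series:
    mask = pd.Series(True, index=df.index)
    for col, vals in selector.items():
        if col not in df.columns:
            raise TableError(
                f"selector column {col!r} not an index of table {table_name!r}")
        if not isinstance(vals, (list, tuple, set, frozenset)):
            vals = [vals]
        allowed = {str(v) for v in vals}
        mask &= df[col].astype(str).isin(allowed)
    return mask


def apply_decisions(
    tables: Mapping[str, IndexedTable],
    decisions: DecisionTable | None,
) -> dict[str, IndexedTable]:
    """Expand externally defined policies into scenario index columns.

    Each targeted table is duplicated along a new index column named after the
    decision; the ``BAU`` level is the untouched table and every other level
    applies that option's changes (in decision-table row order) to the rows
    matched by the selector.  A selector that matches nothing is an error --
    a silent no-op policy is a modelling hazard.
    """
    out = dict(tables)
    if decisions is None or len(decisions) == 0:
        return out
    unknown = set(decisions.rows["Target"]) - set(tables)
    if unknown:
        raise TableError(f"decision targets not in model inputs: {sorted(unknown)}")
    for dname in decisions.decision_names:
        sub = decisions.rows[decisions.rows["Decision"] == dname]
        opts = decisions.options(dname)
        for tname in dict.fromkeys(sub["Target"]):
            t = out[tname]
            if dname in t.data.columns:
                raise TableError(
                    f"decision name {dname!r} clashes with an index column of {tname!r}")
            slices = []
            for opt in opts:
                df = t.data.copy()
                changes = sub[(sub["Option"] == opt) & (sub["Target"] == tname)]
                for row in changes.itertuples(index=False):
                    mask = _selector_mask(df, row.Selector, tname)
                    if not mask.any():
                        raise TableError(
                            f"decision {dname!r} option {opt!r}: selector "
                            f"{row.Selector!r} matches no rows of {tname!r}")
                    if row.Change == "multiply":
                        df.loc[mask, VALUE] *= row.Value
                    elif row.Change == "add":
                        df.loc[mask, VALUE] += row.Value
                    else:  # replace
                        df.loc[mask, VALUE] = row.Value
                df[dname] = opt
                slices.append(df)
            merged = pd.concat(slices, ignore_index=True)
            cols = [c for c in merged.columns if c != VALUE] + [VALUE]
            out[tname] = IndexedTable(
                merged[cols], t.unit, t.name,
                decisions=tuple(dict.fromkeys(t.decisions + (dname,))),
            )
    return out


def scenario_index_of(output: IndexedTable) -> set[str]:
    """The decision columns carried by a model output (empty for a plain run)."""
    return {c for c in output.index_cols if c in output.decisions}
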