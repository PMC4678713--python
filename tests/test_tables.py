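"""Indexed-table arithmetic, aggregation, and the policy/scenario engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from heatburden import (
    AlignmentError,
    DecisionTable,
    IndexedTable,
    TableError,
    align_binary,
    apply_decisions,
    scenario_index_of,
)
from heatburden.tables import ITERATION, VALUE


def table(rows, unit="1", name="t", **kw):
    return IndexedTable(pd.DataFrame(rows), unit=unit, name=name, **kw)


class TestValidation:
    def test_duplicate_index_tuple_rejected(self):
        with pytest.raises(TableError, match="duplicate"):
            table([{"Time": 2010, VALUE: 1.0}, {"Time": 2010, VALUE: 2.0}])

    def test_non_finite_value_rejected(self):
        with pytest.raises(TableError, match="finite"):
            table([{"Time": 2010, VALUE: np.inf}])

    def test_empty_unit_rejected(self):
        with pytest.raises(TableError, match="unit"):
            table([{VALUE: 1.0}], unit="")


class TestAlignBinary:
    def test_scalar_product_on_matching_index(self):
        a = table([{"Time": 2010, VALUE: 2.0}])
        b = table([{"Time": 2010, VALUE: 3.0}])
        out = align_binary(a, b, "*")
        assert out.values.tolist() == [6.0]

    def test_broadcast_over_non_shared_index(self):
        a = table([{"Time": 2010, VALUE: 2.0}], unit="m2")
        b = table([{"Time": 2010, "Fuel": "peat", VALUE: 0.8},
                   {"Time": 2010, "Fuel": "wood", VALUE: 0.2}])
        out = align_binary(a, b, "*")
        assert set(out.index_cols) == {"Time", "Fuel"}
        assert sorted(out.values.tolist()) == [0.4, 1.6]
        assert out.unit == "m2"

    def test_inner_join_drops_unmatched(self):
        a = table([{"T": 1, VALUE: 1.0}, {"T": 2, VALUE: 2.0}])
        b = table([{"T": 2, VALUE: 5.0}, {"T": 3, VALUE: 7.0}])
        out = align_binary(a, b, "+")
        assert out.data.to_dict("records") == [{"T": 2, VALUE: 7.0}]

    def test_disjoint_shared_index_is_an_error(self):
        a = table([{"T": 1, VALUE: 1.0}], name="left")
        b = table([{"T": 9, VALUE: 1.0}], name="right")
        with pytest.raises(AlignmentError, match="T"):
            align_binary(a, b, "+")

    def test_division_by_zero_rejected(self):
        a = table([{VALUE: 1.0}])
        with pytest.raises(TableError, match="zero"):
            align_binary(a, table([{VALUE: 0.0}]), "/")

    def test_unit_combination(self):
        area = table([{VALUE: 2.0}], unit="m2")
        dem = table([{VALUE: 3.0}], unit="kWh/m2/a")
        assert align_binary(area, dem, "*").unit == "m2*kWh/m2/a"
        assert align_binary(area, area, "/").unit == "1"
        share = table([{VALUE: 0.5}], unit="share")
        assert align_binary(area, share, "*").unit == "m2"


small_tables = st.lists(
    st.tuples(st.integers(0, 3), st.floats(-50, 50)), min_size=1, max_size=6,
    unique_by=lambda tv: tv[0],
)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(small_tables, small_tables)
def test_alignment_arithmetic_commutes(ta, tb):
    """+ and × on matching tables agree with a brute-force dict join."""
    a = table([{"K": k, VALUE: v} for k, v in ta])
    b = table([{"K": k, VALUE: v} for k, v in tb])
    da, db = dict(ta), dict(tb)
    shared = set(da) & set(db)
    for op, fn in (("+", lambda x, y: x + y), ("*", lambda x, y: x * y)):
        expected = {k: fn(da[k], db[k]) for k in shared}
        if not shared:
            with pytest.raises(AlignmentError):
                align_binary(a, b, op)
            continue
        out = align_binary(a, b, op)
        got = dict(zip(out.data["K"], out.data[VALUE]))
        assert got == pytest.approx(expected)
        rev = align_binary(b, a, op)
        assert dict(zip(rev.data["K"], rev.data[VALUE])) == pytest.approx(expected)


class TestAggregate:
    def test_sum_over_dropped_indices(self):
        t = table([{"Time": y, "Heating": h, VALUE: v}
                   for (y, h), v in zip(
                       [(2010, "a"), (2010, "b"), (2010, "c"),
                        (2011, "a"), (2011, "b"), (2011, "c")],
                       [1, 2, 3, 10, 20, 30])], unit="m2")
        out = t.aggregate(["Time"])
        assert dict(zip(out.data["Time"], out.data[VALUE])) == {2010: 6, 2011: 60}

    def test_identity_when_all_kept(self):
        t = table([{"Time": 2010, VALUE: 5.0}], unit="m2")
        out = t.aggregate(["Time"])
        pd.testing.assert_frame_equal(out.data, t.data)

    def test_grand_total_conserved_whatever_is_kept(self, rng):
        rows = [{"A": int(a), "B": int(b), "C": int(c),
                 VALUE: float(rng.uniform(0, 9))}
                for a in range(2) for b in range(3) for c in range(2)]
        t = table(rows, unit="m2")
        total = t.data[VALUE].sum()
        for keep in ([], ["A"], ["B"], ["A", "C"], ["A", "B", "C"]):
            assert t.aggregate(keep).data[VALUE].sum() == pytest.approx(total)

    def test_mean_aggregation(self):
        t = table([{"A": 0, VALUE: 2.0}, {"A": 1, VALUE: 4.0}])
        assert t.aggregate([], how="mean").values.tolist() == [3.0]

    def test_dropping_iteration_needs_explicit_flag(self):
        t = table([{ITERATION: 1, VALUE: 1.0}, {ITERATION: 2, VALUE: 3.0}])
        kept = t.aggregate([])
        assert ITERATION in kept.index_cols
        with pytest.raises(TableError):
            t.aggregate([ITERATION], drop_iteration=True)
        dropped = t.aggregate([], drop_iteration=True)
        assert dropped.values.tolist() == [4.0]

    def test_decision_columns_survive_aggregation(self):
        t = table([{"Time": 2010, "Pol": "BAU", VALUE: 1.0},
                   {"Time": 2010, "Pol": "Go", VALUE: 2.0}],
                  decisions=("Pol",))
        out = t.aggregate([])
        assert scenario_index_of(out) == {"Pol"}


def decision_table(rows):
    return DecisionTable(pd.DataFrame(
        rows, columns=["Decision", "Option", "Target", "Selector", "Change", "Value"]))


class TestDecisions:
    def test_empty_decision_table_is_identity(self):
        t = table([{"Fuel": "peat", VALUE: 0.8}], unit="share")
        out = apply_decisions({"mix": t}, decision_table([]))
        assert out["mix"] is t
        assert scenario_index_of(out["mix"]) == set()

    def test_replace_creates_scenario_index_with_intact_bau(self):
        t = table([{"Fuel": "peat", VALUE: 0.8},
                   {"Fuel": "wood", VALUE: 0.2}], unit="share", name="mix")
        dec = decision_table([
            ("Fuel_policy", "Biofuel", "mix", {"Fuel": ["peat"]}, "replace", 0.4),
            ("Fuel_policy", "Biofuel", "mix", {"Fuel": ["wood"]}, "replace", 0.6),
        ])
        out = apply_decisions({"mix": t}, dec)["mix"]
        assert scenario_index_of(out) == {"Fuel_policy"}
        bau = out.select(Fuel_policy="BAU")
        pd.testing.assert_frame_equal(
            bau.data.reset_index(drop=True), t.data, check_like=True)
        pol = out.select(Fuel_policy="Biofuel")
        assert dict(zip(pol.data["Fuel"], pol.data[VALUE])) == {
            "peat": 0.4, "wood": 0.6}

    def test_two_decisions_give_full_factorial(self):
        t = table([{VALUE: 1.0}], unit="1", name="x")
        dec = decision_table([
            ("R", "r1", "x", {}, "multiply", 2.0),
            ("R", "r2", "x", {}, "multiply", 3.0),
            ("F", "f1", "x", {}, "add", 10.0),
        ])
        out = apply_decisions({"x": t}, dec)["x"]
        assert len(out) == 3 * 2
        combos = set(map(tuple, out.data[["R", "F"]].itertuples(index=False)))
        assert len(combos) == 6
        # row order within a decision is apply order: multiply then add
        assert out.select(R="r2", F="f1").values.tolist() == [13.0]

    def test_selector_matching_nothing_is_an_error(self):
        t = table([{"Fuel": "peat", VALUE: 0.8}], unit="share", name="mix")
        dec = decision_table([
            ("F", "go", "mix", {"Fuel": ["uranium"]}, "replace", 1.0)])
        with pytest.raises(TableError, match="matches no rows"):
            apply_decisions({"mix": t}, dec)

    def test_unknown_target_is_an_error(self):
        dec = decision_table([("F", "go", "nope", {}, "replace", 1.0)])
        with pytest.raises(TableError, match="nope"):
            apply_decisions({}, dec)

    def test_bau_option_may_not_carry_changes(self):
        with pytest.raises(TableError, match="BAU"):
            decision_table([("F", "BAU", "x", {}, "replace", 1.0)])
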