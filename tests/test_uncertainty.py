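"""Sampling, deterministic medians, monetization and importance analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from heatburden import (
    IndexedTable,
    InputDistribution,
    MonetizationWeights,
    TableError,
    apply_medians,
    importance,
    importance_ranges,
    incremental_values,
    monetize,
    sample_inputs,
)
from heatburden.tables import ITERATION, VALUE


def scalar_table(v, name):
    return IndexedTable.scalar(v, "1", name)


class TestSampling:
    def test_point_distributions_are_constant(self):
        tables = {"x": scalar_table(5.0, "x")}
        dists = [InputDistribution("x", "x", "point", (7.0,))]
        out, draws = sample_inputs(tables, dists, 100, seed=1)
        assert (out["x"].values == 7.0).all()
        assert draws["x"].nunique() == 1

    def test_same_seed_reproduces_bit_for_bit(self):
        tables = {"x": scalar_table(1.0, "x")}
        dists = [InputDistribution("x", "x", "normal", (100.0, 10.0))]
        _, d1 = sample_inputs(tables, dists, 500, seed=11)
        _, d2 = sample_inputs(tables, dists, 500, seed=11)
        pd.testing.assert_frame_equal(d1, d2)
        _, d3 = sample_inputs(tables, dists, 500, seed=12)
        assert not d1.equals(d3)

    def test_normal_sample_mean_within_clt_bound(self):
        tables = {"x": scalar_table(1.0, "x")}
        dists = [InputDistribution("x", "x", "normal", (100.0, 10.0))]
        _, draws = sample_inputs(tables, dists, 10_000, seed=5)
        se = 10.0 / np.sqrt(10_000)
        assert abs(draws["x"].mean() - 100.0) < 3 * se

    def test_iteration_index_added_with_correct_size(self):
        t = IndexedTable(pd.DataFrame(
            [{"Fuel": "peat", VALUE: 380.0}, {"Fuel": "wood", VALUE: 0.0}]),
            "kg/MWh", "factors")
        dists = [InputDistribution("peat", "factors", "uniform", (300.0, 400.0),
                                   selector={"Fuel": ["peat"]})]
        out, _ = sample_inputs({"factors": t}, dists, 50, seed=3)
        f = out["factors"]
        assert ITERATION in f.index_cols
        assert len(f) == 100
        # untargeted cells replicated unchanged
        assert (f.select(Fuel="wood").values == 0.0).all()

    def test_truncation_clips_support(self):
        dists = [InputDistribution("x", "x", "normal", (0.0, 1.0),
                                   lower=-0.5, upper=0.5)]
        _, draws = sample_inputs({"x": scalar_table(0, "x")}, dists, 2000, seed=2)
        assert draws["x"].between(-0.5, 0.5).all()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(TableError):
            InputDistribution("x", "x", "normal", (0.0, -1.0))
        with pytest.raises(TableError):
            InputDistribution("x", "x", "uniform", (2.0, 1.0))
        with pytest.raises(TableError):
            InputDistribution("x", "x", "triangular", (0.0, 5.0, 1.0))
        with pytest.raises(TableError):
            InputDistribution("x", "x", "gaussian", (0.0, 1.0))


class TestMedians:
    @pytest.mark.parametrize("dist,params,expect", [
        ("point", (3.0,), 3.0),
        ("normal", (100.0, 10.0), 100.0),
        ("lognormal", (0.0, 0.5), 1.0),
        ("uniform", (2.0, 4.0), 3.0),
    ])
    def test_analytic_medians(self, dist, params, expect):
        d = InputDistribution("x", "x", dist, params)
        assert d.median() == pytest.approx(expect)

    def test_triangular_median_matches_scipy(self):
        a, m, b = 1.0, 2.0, 6.0
        d = InputDistribution("x", "x", "triangular", (a, m, b))
        ref = stats.triang.median((m - a) / (b - a), loc=a, scale=b - a)
        assert d.median() == pytest.approx(float(ref))

    def test_apply_medians_is_deterministic_mode(self):
        tables = {"x": scalar_table(1.0, "x")}
        dists = [InputDistribution("x", "x", "normal", (50.0, 5.0))]
        out = apply_medians(tables, dists)
        assert out["x"].values.tolist() == [50.0]
        assert ITERATION not in out["x"].index_cols


class TestMonetize:
    def test_zero_in_zero_out(self):
        z = IndexedTable.scalar(0.0, "t/a")
        zd = IndexedTable.scalar(0.0, "DALY/a")
        assert monetize(z, zd).values.tolist() == [0.0]

    def test_nominal_weights(self):
        co2 = IndexedTable.scalar(1000.0, "t/a")
        daly = IndexedTable.scalar(2.0, "DALY/a")
        out = monetize(co2, daly, MonetizationWeights(15.0, 50_000.0))
        assert out.values.tolist() == [pytest.approx(115_000.0)]
        assert out.unit == "EUR/a"

    def test_linear_in_both_arguments(self):
        w = MonetizationWeights(15.0, 50_000.0)
        one = monetize(IndexedTable.scalar(10.0, "t/a"),
                       IndexedTable.scalar(1.0, "DALY/a"), w)
        two = monetize(IndexedTable.scalar(20.0, "t/a"),
                       IndexedTable.scalar(2.0, "DALY/a"), w)
        assert two.values == pytest.approx(2.0 * one.values)


def value_table(draws_to_value, draws, decisions=()):
    """Build a monetized-output table directly from draws (no model)."""
    frames = []
    if decisions:
        for opt, fn in draws_to_value.items():
            frames.append(pd.DataFrame({
                ITERATION: draws.index, "Pol": opt, VALUE: fn(draws)}))
        df = pd.concat(frames, ignore_index=True)
        return IndexedTable(df, "EUR/a", "value", decisions=("Pol",))
    df = pd.DataFrame({ITERATION: draws.index, VALUE: draws_to_value(draws)})
    return IndexedTable(df, "EUR/a", "value")


class TestImportance:
    def draws(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"driver": rng.normal(1.0, 0.2, n),
             "noise": rng.uniform(0, 1, n)},
            index=pd.Index(np.arange(1, n + 1), name=ITERATION))

    def test_monotone_chain_gives_near_perfect_rank_correlation(self):
        d = self.draws(1000)
        val = value_table(lambda x: np.exp(x["driver"]) * 3.0, d)
        res = importance(d[["driver"]], val)
        assert res["AbsRankCorr"].iloc[0] > 0.99

    def test_independent_input_stays_below_null_bound(self):
        d = self.draws(1000, seed=4)
        val = value_table(lambda x: x["driver"] ** 2, d)
        res = importance(d, val)
        noise = res.set_index("Variable").loc["noise", "AbsRankCorr"]
        assert noise < 0.08  # ~1.96/sqrt(1000)

    def test_zero_variance_input_reported_missing_not_zero(self):
        d = self.draws(100)
        d["flat"] = 1.0
        val = value_table(lambda x: x["driver"], d)
        res = importance(d, val).set_index("Variable")
        assert np.isnan(res.loc["flat", "AbsRankCorr"])

    def test_incremental_mode_is_zero_at_bau(self):
        d = self.draws(200)
        val = value_table(
            {"BAU": lambda x: x["driver"], "Go": lambda x: 2 * x["driver"]},
            d, decisions=("Pol",))
        inc = incremental_values(val)
        bau = inc.select(Pol="BAU").values
        assert (bau == 0.0).all()
        go = inc.select(Pol="Go")
        assert go.values == pytest.approx(
            val.select(Pol="Go").values - val.select(Pol="BAU").values)

    def test_per_combination_results_and_ranges(self):
        d = self.draws(300)
        val = value_table(
            {"BAU": lambda x: x["driver"], "Go": lambda x: -x["driver"]},
            d, decisions=("Pol",))
        res = importance(d[["driver"]], val, mode="absolute")
        assert set(res["Combination"]) == {"Pol=BAU", "Pol=Go"}
        ranges = importance_ranges(res)
        assert (ranges["High"] >= ranges["Low"]).all()

    def test_estimates_tighten_with_sample_size(self):
        """Null-correlation spread shrinks roughly as 1/sqrt(n)."""
        def spread(n):
            vals = []
            for seed in range(20):
                d = self.draws(n, seed=seed)
                val = value_table(lambda x: x["driver"], d)
                res = importance(d, val).set_index("Variable")
                vals.append(res.loc["noise", "AbsRankCorr"])
            return np.std(vals)
        ratio = spread(200) / spread(3200)
        assert 2.0 < ratio < 8.0  # expect ~4 for a 16x sample increase
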