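"""Disparity statistics, quintile assignment, and Q-Q comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import box

from portair import (
    apply_srm,
    assign_income_quintiles,
    grid_to_tracts,
    per_source_disparity,
    qq_compare,
    relative_disparity,
)
from portair.equity import quintile_populations, weighted_quantile
from portair.synthetic import ALL_GROUPS


class TestRelativeDisparity:
    def test_equal_exposure_zero_disparity(self):
        assert relative_disparity(0.5, 0.5) == 0.0

    def test_exposure_ratio_conversions(self):
        # +120% disparity -> 2.2x exposure; +89% -> 1.89 ~ 1.9x
        assert 1.0 + relative_disparity(2.2, 1.0) == pytest.approx(2.2)
        assert 1.0 + relative_disparity(1.89, 1.0) == pytest.approx(1.89)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            relative_disparity(1.0, 0.0)

    @given(st.floats(0.01, 10.0), st.floats(0.01, 10.0), st.floats(0.1, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_uniform_rescaling(self, g, t, alpha):
        assert relative_disparity(alpha * g, alpha * t) == pytest.approx(
            relative_disparity(g, t), rel=1e-9
        )


class TestPerSourceDisparity:
    def test_colocated_group_all_zero(self, tracts, grid, inventory, srm):
        tc = grid_to_tracts(apply_srm(inventory, srm), tracts, grid)
        pops = tracts.set_index("tract_id")["pop_total"]
        res = per_source_disparity(tc, pops, pops)
        assert res.disparity == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.per_source_disparity.to_numpy(), 0.0, atol=1e-12)

    def test_group_next_to_plant_has_max_disparity_from_it(self, grid, srm):
        """Construct a domain where one group lives beside the asphalt
        plant cell: that category tops the group's disparity ranking."""
        from portair.inventory import Inventory, RECORD_COLUMNS

        cells = grid.cells
        plant_cell = cells["cell_id"].iloc[0]
        far_cell = cells["cell_id"].iloc[len(cells) - 1]
        inv = Inventory(pd.DataFrame(
            [("asphalt_plant", "pm25", plant_cell, 1.0, 50.0, ""),
             ("ogv_berth", "pm25", far_cell, 1.0, 50.0, "")],
            columns=RECORD_COLUMNS,
        ))
        field = apply_srm(inv, srm)
        # two one-cell tracts: group lives at the plant, rest far away
        g0 = cells["geometry"].iloc[0]
        g1 = cells["geometry"].iloc[len(cells) - 1]
        tracts = pd.DataFrame({
            "tract_id": ["near", "far"],
            "geometry": [g0, g1],
        })
        tc = grid_to_tracts(field, tracts, grid)
        group = pd.Series([100.0, 0.0], index=tc.values.index)
        total = pd.Series([100.0, 1000.0], index=tc.values.index)
        res = per_source_disparity(tc, group, total)
        assert res.per_source_disparity.index[0] == "asphalt_plant"
        assert res.per_source_disparity["asphalt_plant"] > 0
        # brute-force oracle for the ordering
        oracle = {}
        for cat in tc.categories:
            c = tc.values[cat]
            gm = (c * group).sum() / group.sum()
            tm = (c * total).sum() / total.sum()
            oracle[cat] = (gm - tm) / tm
        expect_order = sorted(oracle, key=oracle.get, reverse=True)
        assert list(res.per_source_disparity.index) == expect_order

    def test_fraction_sources_positive_definition(self, tracts, grid, inventory, srm):
        tc = grid_to_tracts(apply_srm(inventory, srm), tracts, grid)
        tset = tracts.set_index("tract_id")
        res = per_source_disparity(tc, tset["pop_black"], tset["pop_total"])
        ps = res.per_source_disparity
        assert res.fraction_sources_positive == pytest.approx((ps > 0).mean())

    def test_population_weighted_mean_disparity_zero(self, tracts, grid, inventory, srm):
        tc = grid_to_tracts(apply_srm(inventory, srm), tracts, grid)
        tset = tracts.set_index("tract_id")
        num = den = 0.0
        for g in ALL_GROUPS:
            p = tset[f"pop_{g}"]
            if p.sum() == 0:
                continue
            d = per_source_disparity(tc, p, tset["pop_total"]).disparity
            num += p.sum() * d
            den += p.sum()
        assert num / den == pytest.approx(0.0, abs=1e-12)


class TestQuintiles:
    def test_five_equal_tracts_one_per_quintile(self):
        t = pd.DataFrame({
            "tract_id": [f"T{i}" for i in range(5)],
            "geometry": [box(i, 0, i + 1, 1) for i in range(5)],
            "pop_total": [100] * 5,
            "mean_income": [10.0, 20.0, 30.0, 40.0, 50.0],
        })
        out = assign_income_quintiles(t)
        assert list(out.sort_values("mean_income")["quintile"]) == [
            "Q1", "Q2", "Q3", "Q4", "Q5"
        ]

    def test_population_shares_near_20pct(self, tracts):
        out = assign_income_quintiles(tracts)
        qp = quintile_populations(out).sum()
        total = out["pop_total"].sum()
        max_tract = out["pop_total"].max()
        for q in qp.index:
            assert abs(qp[q] - 0.2 * total) <= max_tract  # within one tract of 20%

    def test_cumulative_sum_oracle(self, tracts):
        out = assign_income_quintiles(tracts)
        ranked = out.sort_values(["mean_income", "tract_id"]).reset_index(drop=True)
        cum = ranked["pop_total"].cumsum()
        mid = cum - ranked["pop_total"] / 2
        expect = (mid / out["pop_total"].sum() * 5).astype(int).clip(upper=4)
        got = ranked["quintile"].str[1].astype(int) - 1
        assert (got.to_numpy() == expect.to_numpy()).all()

    def test_all_equal_incomes_tiebreak_fills_quintiles(self):
        t = pd.DataFrame({
            "tract_id": [f"T{i}" for i in range(10)],
            "geometry": [box(i, 0, i + 1, 1) for i in range(10)],
            "pop_total": [10] * 10,
            "mean_income": [42.0] * 10,
        })
        out = assign_income_quintiles(t)
        assert out["quintile"].nunique() == 5
        # tie-break on tract_id: T0, T1 in Q1
        assert set(out.loc[out["quintile"] == "Q1", "tract_id"]) == {"T0", "T1"}

    def test_partition_every_tract_one_quintile(self, tracts):
        out = assign_income_quintiles(tracts)
        assert out["quintile"].notna().all()
        assert set(out["quintile"].unique()) <= {f"Q{i}" for i in range(1, 6)}

    def test_missing_income_rejected(self):
        t = pd.DataFrame({
            "tract_id": ["T0", "T1"],
            "geometry": [box(0, 0, 1, 1)] * 2,
            "pop_total": [1, 1],
            "mean_income": [1.0, np.nan],
        })
        with pytest.raises(ValueError, match="T1"):
            assign_income_quintiles(t)


class TestQQ:
    def test_identical_distributions_on_one_to_one_line(self, tracts, grid, inventory, srm):
        tc = grid_to_tracts(apply_srm(inventory, srm), tracts, grid)
        pops = tracts.set_index("tract_id")["pop_total"]
        qq = qq_compare(tc.total, pops, pops)
        np.testing.assert_allclose(
            qq["group_quantile"], qq["population_quantile"], rtol=1e-12
        )

    def test_uniform_shift_moves_group_quantiles_by_delta(self):
        idx = pd.Index([f"t{i}" for i in range(50)], name="tract_id")
        rng = np.random.default_rng(0)
        conc = pd.Series(rng.uniform(0, 1, 50), index=idx)
        pops = pd.Series(rng.integers(10, 100, 50).astype(float), index=idx)
        delta = 0.25
        qq_base = qq_compare(conc, pops, pops)
        qq_shift = qq_compare(conc + delta, pops, pops)
        np.testing.assert_allclose(
            qq_shift["group_quantile"] - qq_base["group_quantile"], delta, rtol=1e-9
        )

    def test_two_tract_sort_and_index_oracle(self):
        idx = pd.Index(["lo", "hi"], name="tract_id")
        conc = pd.Series([1.0, 3.0], index=idx)
        group = pd.Series([10.0, 30.0], index=idx)
        qq = qq_compare(conc, group, group, percentiles=(25, 50, 75))
        # cdf midpoints: lo at 0.125, hi at 0.625 -> interp
        expect = np.interp([0.25, 0.50, 0.75], [0.125, 0.625], [1.0, 3.0])
        np.testing.assert_allclose(qq["group_quantile"], expect, rtol=1e-12)

    def test_quantiles_nondecreasing(self, tracts, grid, inventory, srm):
        tc = grid_to_tracts(apply_srm(inventory, srm), tracts, grid)
        tset = tracts.set_index("tract_id")
        qq = qq_compare(tc.total, tset["pop_black"], tset["pop_total"])
        assert (np.diff(qq["group_quantile"]) >= -1e-15).all()
        assert (np.diff(qq["population_quantile"]) >= -1e-15).all()

    def test_empty_group_rejected(self):
        idx = pd.Index(["a"], name="tract_id")
        with pytest.raises(ValueError):
            qq_compare(pd.Series([1.0], index=idx),
                       pd.Series([0.0], index=idx),
                       pd.Series([5.0], index=idx))

    @given(st.lists(st.floats(0, 10), min_size=2, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_weighted_quantile_bounded_by_extremes(self, values):
        v = np.array(values)
        w = np.ones_like(v)
        qs = weighted_quantile(v, w, np.array([0.1, 0.5, 0.9]))
        assert (qs >= v.min() - 1e-12).all() and (qs <= v.max() + 1e-12).all()
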