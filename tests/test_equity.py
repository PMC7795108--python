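"""Lorenz/Gini equity statistics, county aggregation and composition tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import medaccess as m


def gini_mad_oracle(values, populations):
    """Population-weighted mean-absolute-difference Gini (independent oracle)."""
    v = np.asarray(values, dtype=float)
    p = np.asarray(populations, dtype=float)
    keep = p > 0
    v, p = v[keep], p[keep]
    mu = np.sum(p * v) / p.sum()
    diffs = np.abs(v[:, None] - v[None, :])
    return float(np.sum(p[:, None] * p[None, :] * diffs) / (2 * p.sum() ** 2 * mu))


def surface(values, label="Sec_T"):
    return m.AccessibilitySurface(label, list(range(len(values))),
                                  np.asarray(values, float))


class TestInvertNormalize:
    def test_hand_arithmetic(self):
        """Costs {10,20,40}: reciprocals {.1,.05,.025} normalise to {1, 1/3, 0}."""
        out = m.invert_normalize(surface([10.0, 20.0, 40.0], "Pri_T"))
        np.testing.assert_allclose(out.values, [1.0, 1.0 / 3.0, 0.0], rtol=1e-12)

    def test_endpoints(self):
        out = m.invert_normalize(surface([5.0, 9.0, 2.0, 7.0], "Pri_T"))
        assert out.values[2] == 1.0  # cheapest cell
        assert out.values[1] == 0.0  # dearest cell

    def test_order_exactly_inverted(self):
        rng = np.random.default_rng(0)
        costs = rng.uniform(1.0, 100.0, size=30)
        out = m.invert_normalize(surface(costs, "Pri_S"))
        assert list(np.argsort(costs)) == list(np.argsort(-out.values))

    def test_non_cost_surfaces_pass_through(self):
        s = surface([1.0, 2.0], "Ter_T")
        assert m.invert_normalize(s) is s

    def test_nonpositive_cost_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            m.invert_normalize(surface([0.0, 1.0], "Pri_T"))


class TestLorenzGini:
    def test_equal_values_gini_zero(self):
        res = m.lorenz_gini([3.0] * 10, np.arange(1.0, 11.0))
        assert res.gini == pytest.approx(0.0, abs=1e-12)

    def test_two_units_half(self):
        """Equal populations holding (0, v): the classic Gini = 0.5 case."""
        res = m.lorenz_gini([0.0, 7.0], [100.0, 100.0])
        assert res.gini == pytest.approx(0.5, rel=1e-12)
        assert res.gini == pytest.approx(gini_mad_oracle([0, 7], [100, 100]), rel=1e-12)

    def test_matches_mad_oracle_random(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(2, 50))
            v = rng.uniform(0.0, 10.0, n)
            p = rng.integers(0, 100, n).astype(float)
            if p.sum() == 0 or np.sum(v * p) == 0:
                continue
            res = m.lorenz_gini(v, p)
            assert res.gini == pytest.approx(gini_mad_oracle(v, p), abs=1e-10)

    def test_curve_geometry(self):
        rng = np.random.default_rng(9)
        res = m.lorenz_gini(rng.uniform(0, 5, 20), rng.uniform(1, 10, 20))
        pts = res.points
        assert pts[0] == pytest.approx([0.0, 0.0])
        assert pts[-1] == pytest.approx([1.0, 1.0])
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= -1e-12)
        assert np.all(pts[:, 1] <= pts[:, 0] + 1e-12)  # on or below the diagonal

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        v=st.lists(st.floats(0.01, 100.0), min_size=2, max_size=20),
        c=st.floats(0.1, 50.0),
    )
    def test_scale_invariance(self, v, c):
        p = np.ones(len(v))
        assert m.lorenz_gini(v, p).gini == pytest.approx(
            m.lorenz_gini(np.asarray(v) * c, p).gini, abs=1e-9)

    def test_replication_invariance(self):
        """Splitting a unit into two identical halves leaves Gini unchanged."""
        v, p = [1.0, 4.0, 9.0], [10.0, 20.0, 30.0]
        v2, p2 = [1.0, 4.0, 4.0, 9.0], [10.0, 10.0, 10.0, 30.0]
        assert m.lorenz_gini(v, p).gini == pytest.approx(
            m.lorenz_gini(v2, p2).gini, abs=1e-12)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            m.lorenz_gini([0.0, 0.0], [10.0, 10.0])


class TestCountyAggregation:
    def test_single_cell_county_identity(self):
        cells = [m.DemandCell(0, 0, 0, 100.0, county_id="a")]
        out = m.aggregate_to_county(surface([4.2]), cells)
        assert out["a"] == pytest.approx(4.2)

    def test_weighted_mean(self):
        cells = [m.DemandCell(0, 0, 0, 100.0, county_id="a"),
                 m.DemandCell(1, 0, 0, 300.0, county_id="a")]
        out = m.aggregate_to_county(surface([4.0, 8.0]), cells)
        assert out["a"] == pytest.approx(7.0)

    def test_uniform_surface(self):
        cells = [m.DemandCell(i, 0, 0, 10.0 * (i + 1), county_id=f"c{i % 3}")
                 for i in range(9)]
        out = m.aggregate_to_county(surface([2.5] * 9), cells)
        np.testing.assert_allclose(out.to_numpy(), 2.5)

    def test_zero_population_county_excluded(self):
        cells = [m.DemandCell(0, 0, 0, 100.0, county_id="a"),
                 m.DemandCell(1, 0, 0, 0.0, county_id="b")]
        out = m.aggregate_to_county(surface([1.0, 2.0]), cells)
        assert "b" not in out.index


class TestGroupCorrelation:
    def test_perfect_linear(self):
        vals = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        ratios = pd.Series([0.1, 0.2, 0.3, 0.4], index=list("abcd"))
        r, p, stars = m.group_correlation(vals, ratios)
        assert r == pytest.approx(1.0)
        assert stars == "**"

    def test_closed_form_small_table(self):
        vals = pd.Series([3.0, 7.0, 1.0, 9.0, 5.0], index=list("abcde"))
        ratios = pd.Series([0.5, 0.2, 0.9, 0.4, 0.3], index=list("abcde"))
        r, _, _ = m.group_correlation(vals, ratios)
        a, b = vals.to_numpy(), ratios.to_numpy()
        expected = np.mean((a - a.mean()) * (b - b.mean())) / (a.std() * b.std())
        assert r == pytest.approx(expected, abs=1e-12)

    def test_stars_thresholds(self):
        rng = np.random.default_rng(11)
        x = pd.Series(rng.normal(size=200))
        weak = pd.Series(x + rng.normal(scale=8.0, size=200))
        _, p, stars = m.group_correlation(x, weak)
        assert stars in ("", "*", "**")
        assert (stars == "**") == (p < 0.01)

    def test_independent_null_rarely_significant(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            a = pd.Series(rng.normal(size=30))
            b = pd.Series(rng.normal(size=30))
            _, p, _ = m.group_correlation(a, b)
            hits += p < 0.05
        assert hits <= 0.1 * n_seeds + 1

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            m.group_correlation(pd.Series([1.0, 1.0, 1.0]),
                                pd.Series([0.1, 0.2, 0.3]))


class TestQuantileComposition:
    @staticmethod
    def cells_with_group(pops, group_counts):
        return [
            m.DemandCell(i, 0, 0, float(p), agricultural_count=float(g))
            for i, (p, g) in enumerate(zip(pops, group_counts))
        ]

    def test_proportional_group_uniform_ratio(self):
        """A group spread proportionally to population shows its global share in every bin."""
        rng = np.random.default_rng(12)
        pops = rng.integers(50, 500, size=40).astype(float)
        cells = self.cells_with_group(pops, 0.3 * pops)
        tbl = m.quantile_composition(surface(rng.uniform(0, 1, 40)), cells,
                                     "agricultural")
        np.testing.assert_allclose(tbl["group_share"].dropna(), 0.3, atol=1e-12)

    def test_shares_sum_to_one(self):
        rng = np.random.default_rng(13)
        pops = rng.integers(1, 100, size=30).astype(float)
        cells = self.cells_with_group(pops, rng.uniform(0, 1, 30) * pops)
        tbl = m.quantile_composition(surface(rng.uniform(0, 1, 30)), cells,
                                     "agricultural")
        sums = (tbl["group_share"] + tbl["complement_share"]).dropna()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_extreme_segregation(self):
        """Group entirely in the lowest-value cells: bottom bin holds all of it."""
        pops = np.full(20, 100.0)
        group = np.zeros(20)
        group[:2] = 100.0  # the two lowest-value cells below
        cells = self.cells_with_group(pops, group)
        vals = np.arange(20, dtype=float)
        tbl = m.quantile_composition(surface(vals), cells, "agricultural")
        assert tbl.loc["0-10", "group_dist"] == pytest.approx(1.0)
        assert tbl.loc["top10", "group_dist"] == pytest.approx(0.0)

    def test_count_weighting_option(self):
        pops = np.array([1000.0] + [10.0] * 19)
        cells = self.cells_with_group(pops, 0.5 * pops)
        vals = np.arange(20, dtype=float)
        t_pop = m.quantile_composition(surface(vals), cells, "agricultural",
                                       weighting="population")
        t_cnt = m.quantile_composition(surface(vals), cells, "agricultural",
                                       weighting="count")
        # the huge low-value cell fills several population-weighted bins
        assert t_pop["group_dist"].isna().sum() > t_cnt["group_dist"].isna().sum()

    def test_bins_must_partition(self):
        with pytest.raises(ValueError, match="partition"):
            m.quantile_composition(surface([1.0, 2.0]),
                                   self.cells_with_group([10, 10], [1, 1]),
                                   "agricultural", bins=[(20, 100)])
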