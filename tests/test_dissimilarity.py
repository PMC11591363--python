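import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from gaitdf.dissimilarity import (
    df_baseline,
    df_cross_group,
    df_pair,
    group_stats,
    percent_difference,
    stars,
)
from gaitdf.errors import (
    InsufficientDataError,
    ShapeError,
    StratificationError,
    UnitError,
)
from tests.conftest import make_curve, random_curves


def brute_force_df(a, b):
    """Independent per-bin loop oracle for the dissimilarity factor."""
    total = 0.0
    n = len(a.x)
    for i in range(n):
        total += (a.x[i] - b.x[i]) ** 2
        total += (a.y[i] - b.y[i]) ** 2
    return total / (2 * n)


class TestDfPair:
    def test_identical_curves_zero(self, rng):
        a = make_curve(rng.normal(size=100), rng.normal(size=100))
        assert df_pair(a, a).df == 0.0

    def test_constant_x_offset(self, rng):
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        a = make_curve(x, y)
        b = make_curve(x + 2.0, y, animal="a1")
        # 100 bins x (2 cm)^2 / 200
        assert df_pair(a, b).df == pytest.approx(2.0, abs=1e-12)

    def test_unit_y_offset(self, rng):
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        assert df_pair(make_curve(x, y), make_curve(x, y + 1.0)).df == pytest.approx(0.5)

    def test_translation_sensitivity_analytic(self, rng):
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        for c in (0.3, 1.7, -2.5):
            val = df_pair(make_curve(x, y), make_curve(x + c, y)).df
            assert val == pytest.approx(c**2 / 2.0, rel=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            a = make_curve(rng.normal(size=100), rng.normal(size=100))
            b = make_curve(rng.normal(size=100), rng.normal(size=100))
            assert df_pair(a, b).df == pytest.approx(brute_force_df(a, b), abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_symmetry_property(self, seed):
        r = np.random.default_rng(seed)
        a = make_curve(r.normal(size=100), r.normal(size=100))
        b = make_curve(r.normal(size=100), r.normal(size=100))
        assert df_pair(a, b).df == df_pair(b, a).df

    def test_rmsd_metric_is_sqrt(self, rng):
        a = make_curve(rng.normal(size=100), rng.normal(size=100))
        b = make_curve(rng.normal(size=100), rng.normal(size=100))
        assert df_pair(a, b, metric="rmsd").df == pytest.approx(np.sqrt(df_pair(a, b).df))

    def test_bin_and_unit_mismatch_rejected(self, rng):
        a = make_curve(np.zeros(100), np.zeros(100))
        b = make_curve(np.zeros(50), np.zeros(50))
        with pytest.raises(ShapeError):
            df_pair(a, b)
        c = make_curve(np.zeros(100), np.zeros(100))
        c.units = "px"
        with pytest.raises(UnitError):
            df_pair(a, c)


class TestCrossGroup:
    def test_cardinality(self, rng):
        exp = random_curves(rng, 3, animal_prefix="e", group="ischemia")
        ctrl = random_curves(rng, 4, animal_prefix="c", group="control")
        mat = df_cross_group(exp, ctrl)
        assert len(mat.values) == 12
        assert mat.scheme == "cross_group"

    def test_identical_collections_give_zero_means(self, rng):
        x, y = rng.normal(size=100), rng.normal(size=100)
        exp = [make_curve(x, y, animal="e0", group="ischemia")]
        ctrl = [make_curve(x, y, animal="c0", group="control")]
        assert df_cross_group(exp, ctrl).mean == 0.0

    def test_matches_pairwise_df_pair(self, rng):
        exp = random_curves(rng, 3, animal_prefix="e", group="ischemia")
        ctrl = random_curves(rng, 3, animal_prefix="c")
        mat = df_cross_group(exp, ctrl)
        direct = {
            (a.keys, b.keys): df_pair(a, b).df for a in exp for b in ctrl
        }
        for v in mat.values:
            assert v.df == pytest.approx(direct[(v.curve_a, v.curve_b)], abs=1e-12)

    def test_cross_stratum_rejected(self, rng):
        exp = [make_curve(np.zeros(100), np.zeros(100), group="ischemia", side="left")]
        ctrl = [make_curve(np.zeros(100), np.zeros(100), side="right")]
        with pytest.raises(StratificationError):
            df_cross_group(exp, ctrl)

    def test_mean_df_monotone_in_attenuation(self, rng):
        template = 1.5 * np.sin(np.pi * np.linspace(0, 1, 100)) ** 2
        ctrl = [
            make_curve(rng.normal(0, 0.05, 100), template + rng.normal(0, 0.05, 100),
                       animal=f"c{i}")
            for i in range(5)
        ]
        means = []
        for att in (0.1, 0.3, 0.5):
            exp = [
                make_curve(
                    rng.normal(0, 0.05, 100),
                    (1 - att) * template + rng.normal(0, 0.05, 100),
                    animal=f"e{i}", group="ischemia",
                )
                for i in range(5)
            ]
            means.append(df_cross_group(exp, ctrl).mean)
        assert means[0] < means[1] < means[2]


class TestBaseline:
    def test_cross_animal_pair_count(self, rng):
        curves = []
        for a in range(2):
            for s in range(2):
                curves.append(
                    make_curve(rng.normal(size=100), rng.normal(size=100),
                               animal=f"c{a}", step=s)
                )
        mat = df_baseline(curves)
        assert len(mat.values) == 4  # 2 steps x 2 steps across the animal pair
        for v in mat.values:
            assert v.curve_a[0] != v.curve_b[0]

    def test_single_animal_rejected(self, rng):
        curves = random_curves(rng, 1)
        with pytest.raises(InsufficientDataError):
            df_baseline(curves)

    def test_noise_floor_matches_analytic_expectation(self, rng):
        """i.i.d. bin noise sigma on both axes of both curves => E[DF] = 2 sigma^2."""
        sigma = 0.08
        template_y = 1.5 * np.sin(np.pi * np.linspace(0, 1, 100)) ** 2
        template_x = np.linspace(0, 8, 100)
        curves = [
            make_curve(
                template_x + rng.normal(0, sigma, 100),
                template_y + rng.normal(0, sigma, 100),
                animal=f"c{a}", step=s,
            )
            for a in range(10)
            for s in range(5)
        ]
        mean_df = df_baseline(curves).mean
        assert mean_df == pytest.approx(2 * sigma**2, rel=0.15)


class TestPercentDifference:
    @pytest.mark.parametrize(
        "exp,ref,expected",
        [(2.7, 1.0, 62.96), (1.0, 1.0, 0.0), (2.0, 1.0, 50.0)],
    )
    def test_declared_definition(self, exp, ref, expected):
        assert percent_difference(exp, ref) == pytest.approx(expected, abs=0.01)

    def test_non_positive_denominator_rejected(self):
        with pytest.raises(InsufficientDataError):
            percent_difference(0.0, 1.0)

    def test_reference_denominator_option(self):
        assert percent_difference(2.0, 1.0, denominator="reference") == pytest.approx(100.0)


class TestGroupStats:
    def test_extreme_separation_significant(self, rng):
        g = {
            "a": 1.0 + rng.normal(0, 1e-6, 4),
            "b": 5.0 + rng.normal(0, 1e-6, 4),
        }
        res = group_stats(g)
        assert res.pairwise[0].p_adjusted <= 0.0001
        assert res.pairwise[0].stars == "****"

    def test_identical_groups_no_stars(self, rng):
        base = rng.normal(0, 1, 12)
        res = group_stats({"a": base, "b": base.copy(), "c": base.copy()})
        for pw in res.pairwise:
            assert pw.p_adjusted > 0.9
            assert pw.stars == ""

    def test_adjusted_p_at_least_raw(self, rng):
        g = {k: rng.normal(0, 1, 8) for k in "abcd"}
        res = group_stats(g)
        assert len(res.pairwise) == 6
        for pw in res.pairwise:
            assert pw.p_adjusted >= pw.p_raw

    def test_kruskal_dunn_against_formula_oracle(self, rng):
        """Dunn z for two groups must match the direct rank computation."""
        g = {"a": rng.normal(0, 1, 9), "b": rng.normal(1, 1, 7)}
        res = group_stats(g, method="kruskal_dunn")
        pooled = np.concatenate([g["a"], g["b"]])
        ranks = sps.rankdata(pooled)
        n = pooled.size
        z_expected = (ranks[:9].mean() - ranks[9:].mean()) / np.sqrt(
            n * (n + 1) / 12.0 * (1 / 9 + 1 / 7)
        )
        assert res.pairwise[0].statistic == pytest.approx(z_expected, abs=1e-10)
        assert res.omnibus_statistic == pytest.approx(
            sps.kruskal(g["a"], g["b"]).statistic
        )

    def test_insufficient_groups_or_values(self, rng):
        with pytest.raises(InsufficientDataError):
            group_stats({"a": [1.0, 2.0]})
        with pytest.raises(InsufficientDataError):
            group_stats({"a": [1.0, 2.0], "b": [1.0]})

    def test_type_i_error_near_nominal(self):
        """Two same-distribution groups: omnibus rejection rate ~ alpha."""
        r = np.random.default_rng(2024)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            res = group_stats({"a": r.normal(0, 1, 10), "b": r.normal(0, 1, 10)})
            rejections += res.omnibus_p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


def test_star_thresholds():
    assert [stars(p) for p in (0.04, 0.009, 0.0009, 0.00009, 0.2)] == [
        "*", "**", "***", "****", "",
    ]
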