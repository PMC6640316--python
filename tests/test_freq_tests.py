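"""Frequentist tests: worked-example values, algebraic identities, oracles."""

import numpy as np
import pytest

from powerref import (ancova_posttest, independent_t, oneway_anova_between,
                      paired_t, pearson_test, posthoc_battery, rm_anova_2x2,
                      rm_anova_oneway, sample_dataset, splitplot_anova_2x2,
                      tost, build_scenario)


class TestPairedT:
    def test_priming_example_values(self, priming):
        res = paired_t(priming["Unrelated"], priming["Related"])
        assert round(float(res.statistic), 2) == 3.04
        assert res.df == (9,)
        assert round(float(res.p_two), 3) == 0.014
        assert round(float(res.effect["dz"]), 2) == 0.96
        assert round(float(res.effect["dav"]), 2) == 0.31

    def test_direct_arithmetic_oracle(self, priming):
        # t = mean(diff) / (SD(diff)/sqrt(n)), computed from scratch
        diff = np.asarray(priming["Priming"], float)
        t_oracle = diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff)))
        res = paired_t(priming["Unrelated"], priming["Related"])
        assert np.isclose(float(res.statistic), t_oracle, rtol=1e-12)

    def test_zero_difference_is_degenerate(self):
        x = np.arange(5.0)
        res = paired_t(x, x)
        assert bool(res.degenerate)
        assert not bool(np.all(res.passed(0.05)))

    def test_one_tailed_p_direction(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        bump = np.array([0.8, 1.1, 0.9, 1.2])
        res_up = paired_t(x + bump, x, direction=1)
        res_down = paired_t(x + bump, x, direction=-1)
        assert float(res_up.p_one) < 0.5 < float(res_down.p_one)
        assert np.isclose(float(res_up.p_one) + float(res_down.p_one), 1.0)


class TestIndependentT:
    def test_hand_oracle(self):
        # pooled sd = sqrt(.5), se = sqrt(.5)*sqrt(1/2+1/2), diff = -1
        res = independent_t([0.0, 1.0], [1.0, 2.0])
        se_oracle = np.sqrt(0.5) * np.sqrt(0.5 + 0.5)
        assert np.isclose(float(res.statistic), -1.0 / se_oracle)
        assert np.isclose(abs(float(res.statistic)), np.sqrt(2.0))
        assert res.df == (2,)

    def test_identical_groups(self):
        g = np.array([1.0, 2.0, 3.0])
        res = independent_t(g, g)
        assert float(res.statistic) == 0.0
        assert np.isclose(float(res.p_two), 1.0)

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(0)
        g1, g2 = rng.normal(size=10), rng.normal(size=10) + 0.5
        a, b = independent_t(g1, g2), independent_t(g2, g1)
        assert np.isclose(float(a.statistic), -float(b.statistic))
        assert np.isclose(float(a.p_two), float(b.p_two))


class TestPearson:
    def test_repeated_example_correlations(self, repeated_wide):
        r12 = pearson_test(repeated_wide["S1"], repeated_wide["S2"])
        assert round(float(r12.effect["r"]), 2) == 0.59
        split = pearson_test(repeated_wide[["S1", "S2"]].mean(axis=1),
                             repeated_wide[["S3", "S4"]].mean(axis=1))
        assert round(float(split.effect["r"]), 2) == 0.74

    def test_perfect_line(self):
        x = np.arange(6.0)
        res = pearson_test(x, 2.0 * x + 1.0)
        assert np.isclose(float(res.effect["r"]), 1.0)


class TestAnovaIdentities:
    def test_f_equals_t_squared_two_groups(self):
        rng = np.random.default_rng(1)
        g1, g2 = rng.normal(size=15), rng.normal(size=15) + 0.4
        F = oneway_anova_between([g1, g2])
        t = independent_t(g1, g2)
        assert np.isclose(float(F.statistic), float(t.statistic) ** 2,
                          atol=1e-10)
        assert np.isclose(float(F.p_two), float(t.p_two), atol=1e-10)

    def test_rm_two_levels_equals_paired_t_squared(self, priming):
        wide = np.stack([priming["Related"], priming["Unrelated"]], axis=1)
        F = rm_anova_oneway(wide)
        t = paired_t(priming["Unrelated"], priming["Related"])
        assert round(float(F.statistic), 2) == 9.24
        assert round(float(F.effect["eta2p"]), 3) == 0.507
        assert np.isclose(float(F.statistic), float(t.statistic) ** 2,
                          atol=1e-10)
        # eta2p = t^2 / (t^2 + df)
        t2 = float(t.statistic) ** 2
        assert np.isclose(float(F.effect["eta2p"]), t2 / (t2 + 9), atol=1e-12)

    def test_three_identical_groups_give_zero_f(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = oneway_anova_between([g, g, g])
        assert np.isclose(float(res.statistic), 0.0)

    def test_all_equal_columns_give_zero_f(self):
        X = np.tile(np.arange(5.0)[:, None], (1, 3))
        res = rm_anova_oneway(X)
        assert np.isclose(float(res.statistic), 0.0)

    def test_rm2x2_effects_equal_contrast_t_squared(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 4)) + [0.4, 0.4, 0.0, 0.0]
        effects = rm_anova_2x2(X)
        cA = (X[:, 0] + X[:, 1] - X[:, 2] - X[:, 3]) / 2.0
        tA = cA.mean() / (cA.std(ddof=1) / np.sqrt(12))
        assert np.isclose(float(effects["A"].statistic), tA ** 2, atol=1e-10)
        flat = rm_anova_2x2(np.tile(np.arange(6.0)[:, None], (1, 4)))
        for eff in flat.values():
            assert np.isclose(float(eff.statistic), 0.0)

    def test_rm_oneway_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 3)) + [0.0, 0.3, 0.6]
        mine = rm_anova_oneway(X)
        long = pd.DataFrame({
            "y": X.ravel(),
            "cond": np.tile(np.arange(3), 10),
            "subj": np.repeat(np.arange(10), 3),
        })
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subj",
                          correction=False)
        assert np.isclose(float(mine.statistic), ref["F"].iloc[0], atol=1e-8)
        assert np.isclose(float(mine.p_two), ref["p_unc"].iloc[0], atol=1e-8)


class TestSplitplot:
    def test_decomposition_identities(self):
        rng = np.random.default_rng(4)
        g1 = rng.normal(size=(14, 2)) + [0.0, 0.4]
        g2 = rng.normal(size=(14, 2)) + [0.0, -0.4]
        res = splitplot_anova_2x2(g1, g2)
        tb = independent_t(g1.mean(1), g2.mean(1))
        assert np.isclose(float(res["between"].statistic),
                          float(tb.statistic) ** 2, atol=1e-10)
        for g in (g1, g2):
            assert res["within"].df == (1, 26)

    def test_against_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(5)
        g1 = rng.normal(size=(9, 2)) + [0.0, 0.5]
        g2 = rng.normal(size=(9, 2))
        mine = splitplot_anova_2x2(g1, g2)
        rows = []
        for gi, g in enumerate((g1, g2)):
            for i in range(g.shape[0]):
                for j in range(2):
                    rows.append((f"{gi}_{i}", gi, j, g[i, j]))
        long = pd.DataFrame(rows, columns=["subj", "group", "cond", "y"])
        ref = pg.mixed_anova(data=long, dv="y", within="cond",
                             subject="subj", between="group")
        ref = ref.set_index("Source")
        assert np.isclose(float(mine["between"].statistic),
                          ref.loc["group", "F"], atol=1e-8)
        assert np.isclose(float(mine["within"].statistic),
                          ref.loc["cond", "F"], atol=1e-8)
        assert np.isclose(float(mine["interaction"].statistic),
                          ref.loc["Interaction", "F"], atol=1e-8)

    def test_identical_groups_and_cells_give_zero(self):
        g = np.tile(np.arange(5.0)[:, None], (1, 2))
        res = splitplot_anova_2x2(g, g.copy())
        assert np.isclose(float(res["within"].statistic), 0.0)
        assert np.isclose(float(res["interaction"].statistic), 0.0)


class TestAncova:
    def test_against_statsmodels_ols(self):
        import statsmodels.formula.api as smf
        import pandas as pd
        rng = np.random.default_rng(6)
        n = 30
        pre = rng.normal(size=2 * n)
        post = 0.5 * pre + rng.normal(size=2 * n)
        post[n:] += 0.4
        group = np.r_[np.zeros(n), np.ones(n)]
        mine = ancova_posttest(pre, post, group)
        df = pd.DataFrame({"pre": pre, "post": post, "group": group})
        fit = smf.ols("post ~ group + pre", df).fit()
        assert np.isclose(float(mine.statistic),
                          fit.tvalues["group"] ** 2, atol=1e-8)
        assert np.isclose(float(mine.p_two), fit.pvalues["group"], atol=1e-10)
        assert mine.df == (1, 2 * n - 3)

    def test_zero_variance_pretest_rejected(self):
        with pytest.raises(ValueError):
            ancova_posttest(np.ones(10), np.arange(10.0),
                            np.r_[np.zeros(5), np.ones(5)])


class TestTost:
    def test_true_null_with_huge_n_declares_equivalence(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=5_000)
        y = rng.normal(size=5_000)
        res = tost("paired", x=x, y=y, bounds=0.2)
        assert bool(res.extra["equivalent"])

    def test_effect_at_bound_gives_p_about_half(self):
        rng = np.random.default_rng(8)
        n = 4_000
        y = rng.normal(size=n)
        x = y + rng.normal(size=n)  # diff SD ~1
        x = x - x.mean() + y.mean() + 0.2 * (x - y).std(ddof=1)
        res = tost("paired", x=x, y=y, bounds=0.2)
        assert 0.4 < float(res.p_two) < 0.6
        assert not bool(res.extra["equivalent"])

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            tost("paired", x=np.arange(5.0), y=np.zeros(5), bounds=-0.1)

    def test_correlation_context(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=3_000)
        y = rng.normal(size=3_000)
        res = tost("correlation", x=x, y=y, bounds=0.1)
        assert bool(res.extra["equivalent"])


class TestPosthocBattery:
    def test_bonferroni_alphas(self):
        sc = build_scenario("three_between_ordered", d=0.4)
        ds = sample_dataset(sc.design, n=30, seed=1)
        out = posthoc_battery(ds, [(((1, 0)), ((0, 0))),
                                   (((2, 0)), ((1, 0))),
                                   (((2, 0)), ((0, 0)))],
                              family_alpha=0.05)
        assert len(out) == 3
        assert all(np.isclose(a, 0.05 / 3) for _, a, _ in out)

    def test_single_contrast_reduces_to_plain_test(self):
        sc = build_scenario("t_within", d=0.4)
        ds = sample_dataset(sc.design, n=20, seed=2)
        [(res, alpha, _)] = posthoc_battery(
            ds, [(((0, 1)), ((0, 0)))], family_alpha=0.05)
        plain = paired_t(ds.data[0, :, 1], ds.data[0, :, 0])
        assert np.isclose(float(res.statistic), float(plain.statistic))
        assert alpha == 0.05

    def test_empty_battery_rejected(self):
        sc = build_scenario("t_within", d=0.4)
        ds = sample_dataset(sc.design, n=20, seed=3)
        with pytest.raises(ValueError):
            posthoc_battery(ds, [])
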