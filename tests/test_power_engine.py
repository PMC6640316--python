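"""Power engine: analytic formulas, Monte-Carlo agreement, minimal-N search."""

import dataclasses

import numpy as np
import pytest

from powerref import (analytic_min_n, analytic_power_correlation,
                      analytic_power_t, analytic_power_tost, build_scenario,
                      find_min_n, mc_power, p_value_bands)
from powerref.scenarios import SuccessCriterion


class TestAnalyticPower:
    def test_paired_examples(self):
        assert analytic_power_t(0.4, 52) >= 0.80 > analytic_power_t(0.4, 51)
        assert round(analytic_power_t(0.4, 100), 2) == 0.98

    def test_null_effect_power_equals_alpha(self):
        assert analytic_power_t(0.0, 40) == pytest.approx(0.05, abs=1e-10)
        assert analytic_power_t(0.0, 40, tails=1) == pytest.approx(0.05,
                                                                   abs=1e-10)

    def test_one_tailed_beats_two_tailed(self):
        assert analytic_power_t(0.4, 41, tails=1) > \
            analytic_power_t(0.4, 41, tails=2)

    def test_correlation_power(self):
        assert analytic_power_correlation(0.2, 194) >= 0.80
        assert analytic_power_correlation(0.2, 193) < 0.80

    def test_tost_methods_straddle_the_published_value(self):
        nct = analytic_power_tost(0.2, 215, "paired")
        assert 0.79 < nct < 0.80
        z = analytic_power_tost(0.2, 215, "paired", method="z")
        assert z >= 0.80


class TestAnalyticMinN:
    @pytest.mark.parametrize("d, tails, kind, expected", [
        (0.4, 2, "independent", 100),
        (0.4, 1, "paired", 41),
        (0.5, 2, "paired", 34),
    ])
    def test_reference_values(self, d, tails, kind, expected):
        assert analytic_min_n(d, 0.8, tails=tails, kind=kind).n == expected

    def test_minn_bracketing_invariant(self):
        res = analytic_min_n(0.4, 0.8, kind="paired")
        assert res.n == 52 and res.estimate >= 0.8
        assert analytic_power_t(0.4, res.n - 1) < 0.8

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValueError):
            analytic_min_n(0.0, 0.8, kind="paired")


class TestPValueBands:
    def test_null_column(self):
        b = p_value_bands(0.0, 100, "paired").as_dict()
        assert b["p >= .10 in line with hypothesis"] == pytest.approx(0.45)
        assert b[".01 <= p < .05 in line with hypothesis"] == \
            pytest.approx(0.02)
        assert b[".001 <= p < .01 against hypothesis"] == \
            pytest.approx(0.0045)
        assert b["p < .001 against hypothesis"] == pytest.approx(0.0005)

    @pytest.mark.parametrize("d", [0.0, 0.3, 0.6])
    @pytest.mark.parametrize("n", [10, 52, 200])
    def test_bands_sum_to_one(self, d, n):
        b = p_value_bands(d, n, "paired")
        assert sum(b.probabilities) == pytest.approx(1.0, abs=1e-9)

    def test_power_property_matches_analytic(self):
        b = p_value_bands(0.4, 100, "paired")
        assert b.power == pytest.approx(analytic_power_t(0.4, 100), abs=1e-9)


class TestMonteCarloAgainstClosedForm:
    @pytest.mark.parametrize("name, kind, d, n", [
        ("t_within", "paired", 0.5, 30),
        ("t_within", "paired", 0.4, 52),
        ("t_between", "independent", 0.4, 50),
        ("t_between", "independent", 0.6, 80),
    ])
    def test_simple_scenarios_match_noncentral_t(self, name, kind, d, n):
        sc = build_scenario(name, d=d)
        est = mc_power(sc, n=n, reps=8_000, seed=21)
        assert abs(est.estimate - analytic_power_t(d, n, kind=kind)) \
            <= 3 * est.se

    def test_mc_power_is_deterministic(self):
        sc = build_scenario("rm2x2_main", d=0.4)
        a = mc_power(sc, n=27, reps=2_000, seed=5)
        b = mc_power(sc, n=27, reps=2_000, seed=5)
        assert a.estimate == b.estimate


class TestFindMinN:
    def test_reproduces_analytic_paired_exactly(self):
        sc = build_scenario("t_within", d=0.4)
        res = find_min_n(sc, 0.8, reps=100_000, seed=1, step=1)
        assert res.n == analytic_min_n(0.4, 0.8, kind="paired").n  # 52

    def test_reproduces_analytic_independent(self):
        sc = build_scenario("t_between", d=0.4)
        res = find_min_n(sc, 0.8, reps=100_000, seed=1, step=1)
        assert abs(res.n - 100) <= 1

    def test_reproduces_analytic_tost(self):
        sc = build_scenario("t_within_null")
        res = find_min_n(sc, 0.8, reps=100_000, seed=1, step=1)
        assert abs(res.n - analytic_min_n(0.0, 0.8, kind="tost_paired").n) <= 1

    def test_correlation_close_to_fisher_z(self):
        # the Fisher-z convention is ~1-2 pairs conservative relative to the
        # exact t-based test the simulation runs
        sc = build_scenario("correlation", d=0.4)
        res = find_min_n(sc, 0.8, reps=100_000, seed=1, step=1)
        assert abs(res.n - 194) <= 2

    def test_bracketing_invariant_on_trace(self):
        sc = build_scenario("rm2x2_main", d=0.4)
        res = find_min_n(sc, 0.8, reps=5_000, seed=3)
        assert res.estimate >= 0.8
        below = dict(res.trace).get(res.n - res.step)
        if below is not None:
            assert below < 0.8

    def test_search_is_deterministic(self):
        sc = build_scenario("splitplot_main_within", d=0.4)
        a = find_min_n(sc, 0.8, reps=3_000, seed=9)
        b = find_min_n(sc, 0.8, reps=3_000, seed=9)
        assert (a.n, a.estimate) == (b.n, b.estimate)

    def test_unreachable_target_raises(self):
        sc = build_scenario("t_within", d=0.0)
        with pytest.raises(RuntimeError):
            find_min_n(sc, 0.8, reps=500, seed=0, n_max=64)


class TestStructuralProperties:
    def test_power_nondecreasing_in_n_and_d(self):
        for d in (0.3, 0.5):
            ests = [mc_power(build_scenario("t_between", d=d), n, reps=4_000,
                             seed=13).estimate for n in (20, 60, 140)]
            assert ests[0] < ests[1] < ests[2]
        ests = [mc_power(build_scenario("rm2x2_main", d=d), 30, reps=4_000,
                         seed=14).estimate for d in (0.2, 0.4, 0.6)]
        assert ests[0] < ests[1] < ests[2]

    def test_conjunction_power_bounded_by_each_requirement(self):
        sc = build_scenario("rm2x2_interaction_null_cell", d=0.4)
        full = mc_power(sc, n=80, reps=6_000, seed=15)
        for i in range(len(sc.criterion)):
            single = dataclasses.replace(
                sc, criterion=SuccessCriterion((sc.criterion.requirements[i],)))
            solo = mc_power(single, n=80, reps=6_000, seed=15)
            assert full.estimate <= solo.estimate + 3 * (full.se + solo.se)

    def test_equal_answers_for_r5_and_r9_when_dz_fixed(self):
        # the within-participant correlation is irrelevant once dz is fixed
        a = mc_power(build_scenario("t_within", d=0.4, r=0.5), 52,
                     reps=8_000, seed=16)
        b = mc_power(build_scenario("t_within", d=0.4, r=0.9), 52,
                     reps=8_000, seed=17)
        assert abs(a.estimate - b.estimate) <= 3 * (a.se + b.se)
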