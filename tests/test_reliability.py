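"""Intraclass correlations and the Spearman-Brown prophecy."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from powerref import (icc, icc_by_condition, required_multiplier,
                      required_observations, spearman_brown)
from powerref.reliability import _anova_icc, _reml_icc


class TestIccWorkedExample:
    def test_icc_values(self, repeated_long):
        rep = icc(repeated_long)
        assert round(rep.icc1, 2) == 0.39
        assert round(rep.icc2, 2) == 0.72
        assert rep.k == 4 and rep.n_participants == 6
        assert rep.method == "anova"

    def test_icc2_is_spearman_brown_of_icc1(self, repeated_long):
        rep = icc(repeated_long)
        assert round(spearman_brown(rep.icc1, 4), 3) == round(rep.icc2, 3)

    def test_required_observations_for_good_reliability(self, repeated_long):
        rep = icc(repeated_long)
        # on the 2-decimal reliability the textbook arithmetic gives 1.56
        assert round(required_multiplier(round(rep.icc2, 2), 0.8), 2) == 1.56
        assert required_observations(rep.icc2, 4, 0.8) == 6
        assert required_observations(rep.icc2, 4, 0.8, safe=True) == 7

    def test_reml_and_anova_agree_on_balanced_data(self, repeated_long):
        vb_a, vw_a, k_a, _ = _anova_icc(repeated_long)
        vb_r, vw_r, k_r, _ = _reml_icc(repeated_long)
        assert math.isclose(vb_a / (vb_a + vw_a), vb_r / (vb_r + vw_r),
                            abs_tol=1e-6)
        assert k_a == k_r == 4

    def test_missing_rows_fall_back_to_reml(self, repeated_long):
        rep = icc(repeated_long.iloc[:-1])
        assert rep.method == "reml"
        assert 0.2 < rep.icc1 < 0.6
        assert rep.k < 4


class TestSpearmanBrown:
    @pytest.mark.parametrize("r, n, expected", [(0.39, 4, 0.72)])
    def test_step_up_example(self, r, n, expected):
        assert round(spearman_brown(r, n), 2) == expected

    def test_identity_and_limit(self):
        assert spearman_brown(0.37, 1) == pytest.approx(0.37)
        assert spearman_brown(0.5, 1e9) == pytest.approx(1.0, abs=1e-8)

    def test_fewer_needed_when_already_reliable(self):
        assert required_multiplier(0.8, 0.8) == pytest.approx(1.0)
        assert required_multiplier(0.9, 0.8) < 1.0

    @given(st.floats(0.05, 0.95), st.floats(0.05, 0.95))
    @settings(derandomize=True, max_examples=100)
    def test_multiplier_inverts_spearman_brown(self, r_obs, r_des):
        n = required_multiplier(r_obs, r_des)
        assert math.isclose(spearman_brown(r_obs, n), r_des, abs_tol=1e-10)

    def test_invalid_reliabilities(self):
        with pytest.raises(ValueError):
            required_multiplier(0.0, 0.8)
        with pytest.raises(ValueError):
            spearman_brown(1.0, 2)


class TestIccEdgeCases:
    def test_perfectly_reliable_participants(self):
        long = pd.DataFrame({
            "Participant": ["a", "a", "b", "b", "c", "c"],
            "Response": [1.0, 1.0, 5.0, 5.0, 9.0, 9.0],
        })
        assert icc(long).icc1 == pytest.approx(1.0)

    def test_all_identical_responses_undefined(self):
        long = pd.DataFrame({
            "Participant": ["a", "a", "b", "b"],
            "Response": [2.0, 2.0, 2.0, 2.0],
        })
        with pytest.raises(ValueError, match="identical"):
            icc(long)

    def test_single_observation_per_participant_rejected(self):
        long = pd.DataFrame({"Participant": ["a", "b", "c"],
                             "Response": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            icc(long)

    def test_negative_variance_truncated_with_warning(self):
        # anti-correlated repeats: within-variance dwarfs between-variance
        long = pd.DataFrame({
            "Participant": list("aabbccdd"),
            "Response": [1.0, 9.0, 2.0, 8.0, 1.5, 8.5, 2.2, 8.8],
        })
        with pytest.warns(UserWarning, match="truncated"):
            rep = icc(long)
        assert rep.icc1 == 0.0
        assert rep.icc1_untruncated < 0.0


class TestIccByCondition:
    @staticmethod
    def _long(participants, conditions, responses):
        return pd.DataFrame({"Participant": participants,
                             "Condition": conditions,
                             "Response": responses})

    def test_group_gap_inflates_dataset_wide_icc(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(6):
            base = 0.0 if i < 3 else 10.0   # two well-separated groups
            cond = "low" if i < 3 else "high"
            for rep in range(4):
                rows.append((f"p{i}", cond, base + rng.normal(scale=1.0)))
        long = pd.DataFrame(rows, columns=["Participant", "Condition",
                                           "Response"])
        per, overall = icc_by_condition(long)
        assert overall.icc1 > 0.8
        assert all(rep.icc1 < 0.5 for rep in per.values())

    def test_negatively_correlated_conditions_hurt_pooled_icc(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(8):
            level = rng.normal(scale=2.0)
            for rep in range(3):
                rows.append((f"p{i}", "pos", level + rng.normal(scale=0.3)))
                rows.append((f"p{i}", "neg", -level + rng.normal(scale=0.3)))
        long = pd.DataFrame(rows, columns=["Participant", "Condition",
                                           "Response"])
        per, overall = icc_by_condition(long)
        mean_within = np.mean([rep.icc1 for rep in per.values()])
        assert overall.icc1 < mean_within

    def test_homogeneous_conditions_agree_with_pooled(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(10):
            level = rng.normal(scale=1.5)
            for cond in ("a", "b"):
                for rep in range(4):
                    rows.append((f"p{i}", cond,
                                 level + rng.normal(scale=0.8)))
        long = pd.DataFrame(rows, columns=["Participant", "Condition",
                                           "Response"])
        per, overall = icc_by_condition(long)
        for rep in per.values():
            assert abs(rep.icc1 - overall.icc1) < 0.15

    def test_missing_condition_column_rejected(self, repeated_long):
        long = repeated_long.drop(columns="Condition")
        with pytest.raises(ValueError):
            icc_by_condition(long)
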