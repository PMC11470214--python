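"""Descriptives, Kruskal-Wallis / Conover-Iman, TIW regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kruskal

import vioscales as v
from vioscales.cohort import Cohort

from conftest import zero_noise_config


def _scale_cohort(values, physicians=None):
    n = len(values)
    df = pd.DataFrame(
        {
            "patient_id": range(n),
            "physician_id": physicians if physicians is not None else [0] * n,
            "pain_assault": pd.array(values, dtype="Int64"),
        }
    )
    for col in v.SCALE_COLUMNS:
        if col not in df.columns:
            df[col] = pd.array([0] * n, dtype="Int64")
    return Cohort(df)


class TestDescribe:
    def test_odd_length_exact_quartiles(self):
        cohort = _scale_cohort([1, 2, 3, 4, 5])
        table = v.describe_by_profile(cohort, np.array(["p"] * 5))
        cell = table.loc[table["variable"] == "pain_assault", "p"].iloc[0]
        assert cell == "3 (2-4)"

    def test_constant_column_has_zero_iqr_width(self):
        cohort = _scale_cohort([4, 4, 4, 4])
        table = v.describe_by_profile(cohort, np.array(["p"] * 4))
        cell = table.loc[table["variable"] == "pain_assault", "p"].iloc[0]
        assert cell == "4 (4-4)"

    def test_zero_noise_profile_e_fear_median_is_six(self):
        """The IPV-dominated profile is configured with maximal fear during
        the assault; without noise its median is exactly 6."""
        cohort = v.generate_cohort(zero_noise_config(n_patients=400, seed=9))
        labels = cohort.df["true_profile"].to_numpy()
        table = v.describe_by_profile(cohort, labels)
        cell = table.loc[table["variable"] == "fear_assault", "E"].iloc[0]
        assert cell.startswith("6 (")


class TestKruskalWallis:
    def test_hand_example(self):
        res = v.kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.statistic == pytest.approx(27 / 7)
        assert res.df == 1

    def test_identical_groups_give_zero(self):
        res = v.kruskal_wallis([[2, 2, 2], [2, 2, 2]])
        assert res.statistic == 0.0
        assert res.p_raw == 1.0

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(50):
            groups = [rng.integers(0, 7, size=rng.integers(5, 15)) for _ in range(3)]
            if len(np.unique(np.concatenate(groups))) < 2:
                continue
            ours = v.kruskal_wallis(groups)
            ref = kruskal(*groups)
            assert ours.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert ours.p_raw == pytest.approx(ref.pvalue, rel=1e-10)

    def test_invariant_under_monotone_transform(self, rng):
        groups = [rng.integers(0, 7, 20).astype(float) for _ in range(3)]
        a = v.kruskal_wallis(groups).statistic
        b = v.kruskal_wallis([np.exp(g) for g in groups]).statistic
        assert a == pytest.approx(b, abs=1e-10)


class TestConover:
    def test_hand_example(self):
        table = v.conover_posthoc([[1, 2, 3], [4, 5, 6]])
        assert abs(table.loc[0, "statistic"]) == pytest.approx(3.674, abs=1e-3)
        assert table.loc[0, "df"] == 4

    def test_identical_groups_null_result(self):
        table = v.conover_posthoc([[3, 3, 3], [3, 3, 3]])
        assert table.loc[0, "statistic"] == 0.0
        assert table.loc[0, "p_adjusted"] == 1.0

    def test_bonferroni_is_three_times_raw_for_three_groups(self, rng):
        groups = [rng.normal(loc=m, size=10) for m in (0.0, 0.3, 0.8)]
        table = v.conover_posthoc(groups)
        assert len(table) == 3
        for _, row in table.iterrows():
            assert row["p_adjusted"] == pytest.approx(min(1.0, 3 * row["p_raw"]))
            assert row["p_adjusted"] >= row["p_raw"]


class TestRegression:
    def test_noiseless_line_has_exact_slope_and_zero_width_ci(self):
        df = pd.DataFrame(
            {
                "patient_id": range(7),
                "pain_assault": pd.array(range(7), dtype="Int64"),
                "tiw_days": pd.array([2 * x for x in range(7)], dtype="Int64"),
            }
        )
        res = v.ols_univariate(Cohort(df), "pain_assault")
        assert res.beta == pytest.approx(2.0)
        assert res.ci_high - res.ci_low == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_slope(self):
        df = pd.DataFrame(
            {
                "patient_id": range(3),
                "pain_assault": pd.array([1, 2, 3], dtype="Int64"),
                "tiw_days": pd.array([1, 3, 2], dtype="Int64"),
            }
        )
        res = v.ols_univariate(Cohort(df), "pain_assault")
        assert res.beta == pytest.approx(0.5)
        assert res.ci_low <= res.beta <= res.ci_high
        assert res.n == 3

    def test_zero_variance_rejected(self):
        df = pd.DataFrame(
            {
                "patient_id": range(5),
                "pain_assault": pd.array([3] * 5, dtype="Int64"),
                "tiw_days": pd.array([1, 2, 3, 4, 5], dtype="Int64"),
            }
        )
        with pytest.raises(ValueError, match="zero variance"):
            v.ols_univariate(Cohort(df), "pain_assault")


class TestPhysicianComparison:
    def test_unbiased_physicians_rarely_flagged(self):
        """With zero physician bias and identical case mixes the number of
        significant Bonferroni-adjusted pairs stays at the null level."""
        cfg = v.default_config(n_patients=1500, seed=21, missing_rate=0.0,
                               rater_bias_sd=0.0)
        cohort = v.generate_cohort(cfg)
        labels = cohort.df["true_profile"].to_numpy()
        comp = v.physician_rating_comparison(cohort, labels, "pain_assault")
        assert comp["overall"]["n_significant_pairs"] <= 3  # ~alpha * 45 pairs

    def test_casemix_confounding_inflates_overall_differences(self):
        """Physicians with different profile mixes but no bias: the overall
        comparison flags more pairs than the within-profile comparisons."""
        wins = 0
        for i in range(20):
            cfg = v.default_config(n_patients=1200, seed=400 + i, missing_rate=0.0,
                                   rater_bias_sd=0.0, n_physicians=4)
            cohort = v.generate_cohort(cfg)
            df = cohort.df
            # skew case mix: physician j preferentially sees profile j
            prof_idx = pd.Categorical(df["true_profile"]).codes
            reassign = np.where(np.random.default_rng(i).random(len(df)) < 0.6,
                                np.minimum(prof_idx, 3), df["physician_id"])
            df["physician_id"] = reassign
            labels = df["true_profile"].to_numpy()
            comp = v.physician_rating_comparison(cohort, labels, "fear_assault")
            overall = comp["overall"]["n_significant_pairs"]
            within = max((r["n_significant_pairs"] for r in comp["per_profile"].values()),
                         default=0)
            wins += overall >= within
        assert wins >= 15

    def test_planted_bias_flagged_within_every_profile(self):
        """A physician shifted by +2 points stands out within each profile."""
        cfg = v.default_config(n_patients=3000, seed=33, missing_rate=0.0,
                               rater_bias_sd=0.0, n_physicians=4)
        cohort = v.generate_cohort(cfg)
        df = cohort.df
        biased = (df["physician_id"] == 0).to_numpy()
        df["pain_assault"] = pd.array(
            np.clip(df["pain_assault"].to_numpy(int) + 2 * biased, 0, 6), dtype="Int64"
        )
        labels = df["true_profile"].to_numpy()
        comp = v.physician_rating_comparison(cohort, labels, "pain_assault")
        for profile, res in comp["per_profile"].items():
            pw = res["pairwise"]
            flagged = pw[(pw["physician_i"] == 0) | (pw["physician_j"] == 0)]
            assert (flagged["p_adjusted"] < 0.05).all(), profile
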