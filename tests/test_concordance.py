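"""Tie-corrected Kendall W, profile-matched pairing, repeated matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata, spearmanr

import vioscales as v
from vioscales.cohort import Cohort

from conftest import zero_noise_config


class TestRanks:
    def test_one_tie_pair(self):
        ranks, tie = v.rank_with_ties([0, 1, 1])
        assert ranks.tolist() == [1, 2.5, 2.5]
        assert tie == 6.0

    def test_all_distinct_has_zero_tie_term(self):
        ranks, tie = v.rank_with_ties([3, 1, 2])
        assert ranks.tolist() == [3, 1, 2]
        assert tie == 0.0

    def test_matches_sort_based_reference(self, rng):
        """Independent oracle: assign each value the mean of the sorted
        positions it occupies."""
        for _ in range(500):
            vals = rng.integers(0, 5, size=rng.integers(1, 12))
            ranks, tie = v.rank_with_ties(vals)
            order = np.argsort(vals, kind="stable")
            ref = np.empty(len(vals))
            i = 0
            while i < len(vals):
                j = i
                while j < len(vals) and vals[order[j]] == vals[order[i]]:
                    j += 1
                ref[order[i:j]] = (i + j + 1) / 2.0
                i = j
            assert np.allclose(ranks, ref)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            v.rank_with_ties([])


class TestKendallW:
    def test_perfect_agreement(self):
        assert v.kendall_w(np.array([[0, 0], [3, 3], [5, 5]])) == pytest.approx(1.0)

    def test_reversed_untied_columns(self):
        assert v.kendall_w(np.array([[1, 3], [2, 2], [3, 1]])) == pytest.approx(0.0)

    def test_worked_tie_example(self):
        """S=4.5, sum T=12, denominator 72 -> W=0.75."""
        w = v.kendall_w(np.array([[0, 1], [1, 1], [1, 2]]))
        assert w == pytest.approx(0.75)

    def test_spearman_identity_for_two_untied_raters(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 15))
            a = rng.permutation(n).astype(float)
            b = rng.permutation(n).astype(float)
            w = v.kendall_w(np.column_stack([a, b]))
            rho = spearmanr(a, b).statistic
            assert abs(w - (rho + 1) / 2) < 1e-12

    def test_degenerate_constant_raters_raise(self):
        with pytest.raises(v.DegenerateRatingsError):
            v.kendall_w(np.array([[2, 2], [2, 2], [2, 2]]))

    def test_invariant_under_monotone_transform_of_one_rater(self, rng):
        scores = rng.integers(0, 7, size=(20, 2)).astype(float)
        w0 = v.kendall_w(scores)
        transformed = scores.copy()
        transformed[:, 1] = np.exp(transformed[:, 1]) + 5
        assert v.kendall_w(transformed) == pytest.approx(w0, abs=1e-12)

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(
            st.tuples(st.integers(0, 6), st.integers(0, 6), st.integers(0, 6)),
            min_size=2,
            max_size=15,
        )
    )
    def test_w_bounded_between_zero_and_one(self, rows):
        mat = np.array(rows, dtype=float)
        try:
            w = v.kendall_w(mat)
        except v.DegenerateRatingsError:
            return
        assert -1e-12 <= w <= 1 + 1e-12


def _matching_cohort():
    """8 patients, 2 physicians, 2 profiles, hand-set scores."""
    df = pd.DataFrame(
        {
            "patient_id": list(range(8)),
            "physician_id": [0, 0, 0, 0, 1, 1, 1, 1],
            "pain_assault": pd.array([1, 2, 5, 6, 2, 1, 6, 5], dtype="Int64"),
        }
    )
    labels = pd.Series(["a", "a", "b", "b", "a", "a", "b", "b"],
                       index=df["patient_id"])
    return Cohort(df), labels


class TestInterraterMatching:
    def test_pair_count_is_min_of_the_two_sides(self):
        df = pd.DataFrame(
            {
                "patient_id": range(8),
                "physician_id": [0, 0, 0, 1, 1, 1, 1, 1],
            }
        )
        labels = pd.Series(["a"] * 8, index=df["patient_id"])
        matched = v.match_interrater(Cohort(df), labels, 0, 1, seed=0)
        assert len(matched) == 3
        ids_a = {a for a, _, _ in matched.pairs}
        ids_b = {b for _, b, _ in matched.pairs}
        assert ids_a <= {0, 1, 2} and ids_b <= {3, 4, 5, 6, 7}

    def test_disjoint_profiles_raise(self):
        cohort, _ = _matching_cohort()
        labels = pd.Series(["a", "a", "a", "a", "b", "b", "b", "b"],
                           index=cohort.df["patient_id"])
        with pytest.raises(ValueError, match="share no profile"):
            v.match_interrater(cohort, labels, 0, 1, seed=0)

    def test_bijections_drawn_uniformly(self):
        """2 x 2 case: both possible bijections occur at ~1/2."""
        df = pd.DataFrame({"patient_id": range(4), "physician_id": [0, 0, 1, 1]})
        labels = pd.Series(["a"] * 4, index=df["patient_id"])
        cohort = Cohort(df)
        hits = 0
        for seed in range(2000):
            matched = v.match_interrater(cohort, labels, 0, 1, seed=seed)
            pairing = {a: b for a, b, _ in matched.pairs}
            hits += pairing[0] == 2
        assert abs(hits / 2000 - 0.5) <= 0.03


class TestIntraraterMatching:
    def test_odd_count_drops_one(self):
        df = pd.DataFrame({"patient_id": range(5), "physician_id": [0] * 5})
        labels = pd.Series(["a"] * 5, index=df["patient_id"])
        matched = v.match_intrarater(Cohort(df), labels, 0, seed=0)
        assert len(matched) == 2
        used = [x for a, b, _ in matched.pairs for x in (a, b)]
        assert len(used) == len(set(used))

    def test_two_patients_one_pair(self):
        df = pd.DataFrame({"patient_id": [7, 9], "physician_id": [0, 0]})
        labels = pd.Series(["a", "a"], index=df["patient_id"])
        assert len(v.match_intrarater(Cohort(df), labels, 0, seed=1)) == 1

    def test_no_pairable_profile_raises(self):
        df = pd.DataFrame({"patient_id": [1, 2], "physician_id": [0, 0]})
        labels = pd.Series(["a", "b"], index=df["patient_id"])
        with pytest.raises(ValueError):
            v.match_intrarater(Cohort(df), labels, 0, seed=0)

    def test_perfect_matchings_drawn_uniformly(self):
        """4 patients: each of the 3 perfect matchings occurs at ~1/3."""
        df = pd.DataFrame({"patient_id": range(4), "physician_id": [0] * 4})
        labels = pd.Series(["a"] * 4, index=df["patient_id"])
        cohort = Cohort(df)
        counts: dict = {}
        for seed in range(3000):
            matched = v.match_intrarater(cohort, labels, 0, seed=seed)
            key = frozenset(frozenset((a, b)) for a, b, _ in matched.pairs)
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 3
        for c in counts.values():
            assert abs(c / 3000 - 1 / 3) <= 0.03


class TestConcordanceAnalysis:
    def test_zero_noise_cohort_has_perfect_pooled_w(self):
        cohort = v.generate_cohort(zero_noise_config(n_patients=400, seed=6,
                                                     n_physicians=2))
        labels = cohort.df.set_index("patient_id")["true_profile"]
        res = v.concordance_analysis(cohort, labels, "fear_assault", [(0, 1)],
                                     repetitions=5, seed=0)
        assert res[(0, 1)].pooled_W == pytest.approx(1.0)

    def test_independent_uniform_scores_give_half(self, rng):
        """Under rater independence E(W) -> 1/2 for m=2."""
        n = 400
        df = pd.DataFrame(
            {
                "patient_id": range(n),
                "physician_id": [0] * (n // 2) + [1] * (n // 2),
                "pain_assault": pd.array(rng.integers(0, 7, n), dtype="Int64"),
            }
        )
        labels = pd.Series(["a"] * n, index=df["patient_id"])
        res = v.concordance_analysis(Cohort(df), labels, "pain_assault", [(0, 1)],
                                     repetitions=200, seed=1)
        assert res[(0, 1)].pooled_W == pytest.approx(0.5, abs=0.05)

    def test_undefined_cells_reported_not_dropped(self):
        """Constant scores make every rating column degenerate: W is
        reported as undefined for each repetition, never as a number."""
        df = pd.DataFrame(
            {
                "patient_id": range(8),
                "physician_id": [0, 0, 0, 0, 1, 1, 1, 1],
                "pain_assault": pd.array([3] * 8, dtype="Int64"),
            }
        )
        labels = pd.Series(["a"] * 8, index=df["patient_id"])
        res = v.concordance_analysis(Cohort(df), labels, "pain_assault", [(0, 1)],
                                     repetitions=3, seed=0)
        r = res[(0, 1)]
        assert r.n_undefined == 3
        assert np.isnan(r.pooled_W)

    def test_missing_scores_excluded_pairwise(self):
        cohort, labels = _matching_cohort()
        cohort.df.loc[0, "pain_assault"] = pd.NA
        res = v.concordance_analysis(cohort, labels, "pain_assault", [(0, 1)],
                                     repetitions=4, seed=2)
        assert res[(0, 1)].repetitions == 4  # runs despite the missing score

    def test_pooled_equals_profile_w_with_single_profile(self, rng):
        n = 60
        df = pd.DataFrame(
            {
                "patient_id": range(n),
                "physician_id": [0] * (n // 2) + [1] * (n // 2),
                "pain_assault": pd.array(rng.integers(0, 7, n), dtype="Int64"),
            }
        )
        labels = pd.Series(["only"] * n, index=df["patient_id"])
        res = v.concordance_analysis(Cohort(df), labels, "pain_assault", [(0, 1)],
                                     repetitions=10, seed=3)
        r = res[(0, 1)]
        assert r.pooled_W == pytest.approx(r.per_profile_W["only"], abs=1e-12)


class TestSensitivity:
    def test_fine_profiles_preserve_perfect_agreement(self):
        cfg = zero_noise_config(n_patients=120, seed=4, n_physicians=2)
        fp = {pr: {f: (1.0 if p >= 0.5 else 0.0) for f, p in t.items()}
              for pr, t in cfg.feature_probs.items()}
        cohort = v.generate_cohort(cfg.with_overrides(feature_probs=fp))
        labels = cohort.df.set_index("patient_id")["true_profile"]
        dm = v.gower_dissimilarity(cohort)
        out = v.sensitivity_fine_profiles(cohort, dm, labels, "fear_assault",
                                          [(0, 1)], repetitions=3, seed=5,
                                          n_profiles_large=60)
        assert out["W_base"].iloc[0] == pytest.approx(1.0)
        assert out["W_fine"].iloc[0] == pytest.approx(1.0)

    def test_k_large_capped_at_half_n(self, small_cohort):
        labels = small_cohort.df.set_index("patient_id")["true_profile"]
        dm = v.gower_dissimilarity(small_cohort)
        with pytest.raises(ValueError):
            v.sensitivity_fine_profiles(small_cohort, dm, labels, "pain_assault",
                                        [(0, 1)], n_profiles_large=300)

    def test_finer_typology_does_not_lower_agreement(self):
        """When coarse profiles hide systematic sub-profile differences,
        matching within finer profiles cannot hurt (and usually helps)
        agreement: mean delta W >= -0.02 across replicates."""
        deltas = []
        for i in range(10):
            cfg = v.default_config(n_patients=500, seed=800 + i, missing_rate=0.0,
                                   n_physicians=2)
            cohort = v.generate_cohort(cfg)
            labels = cohort.df.set_index("patient_id")["true_profile"]
            dm = v.gower_dissimilarity(cohort)
            out = v.sensitivity_fine_profiles(cohort, dm, labels, "fear_assault",
                                              [(0, 1)], repetitions=5, seed=i,
                                              n_profiles_large=100)
            deltas.append(out["delta"].iloc[0])
        assert np.mean(deltas) >= -0.02
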