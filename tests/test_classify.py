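"""FDR ranking and incremental SVM evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.svm import SVC

from parkdiff import (CVConfig, FeatureMatrix, SVMConfig,
                      fisher_discriminant_ratio, incremental_svm_accuracy,
                      independent_validation, leave_two_out_cv, pair_label,
                      rank_features)


class TestFDR:
    def test_hand_oracle(self):
        # (2 - 5)^2 / (1 + 1) with sample variances of {1,2,3} and {4,5,6}
        assert fisher_discriminant_ratio([1, 2, 3], [4, 5, 6]) == pytest.approx(4.5)

    def test_equal_distributions_score_zero(self):
        assert fisher_discriminant_ratio([1, 2, 3], [1, 2, 3]) == 0.0

    @settings(deadline=None, max_examples=30)
    @given(scale=st.floats(0.1, 50), shift=st.floats(-20, 20),
           seed=st.integers(0, 50))
    def test_common_affine_invariance(self, scale, shift, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=6), rng.normal(2, 1, size=6)
        base = fisher_discriminant_ratio(a, b)
        moved = fisher_discriminant_ratio(scale * a + shift, scale * b + shift)
        assert moved == pytest.approx(base, rel=1e-9)

    def test_symmetry_and_degenerate_cases(self):
        assert fisher_discriminant_ratio([1, 2], [5, 9]) == \
            fisher_discriminant_ratio([5, 9], [1, 2])
        assert fisher_discriminant_ratio([3, 3], [3, 3]) == 0.0
        assert fisher_discriminant_ratio([1, 1], [2, 2]) == np.inf
        with pytest.raises(ValueError):
            fisher_discriminant_ratio([1], [2, 3])


class TestRanking:
    def _fm(self, data, ids):
        return FeatureMatrix(pd.DataFrame(data, index=ids))

    def test_informative_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        ids = [f"s{i}" for i in range(16)]
        labels = pd.Series(["Control"] * 8 + ["PD"] * 8, index=ids)
        data = pd.DataFrame(rng.normal(size=(16, 8)), index=ids,
                            columns=[f"GMvol:f{i}" for i in range(8)])
        data.loc[labels == "PD", "GMvol:f3"] += 6.0
        ranking = rank_features(FeatureMatrix(data), labels)
        assert ranking.features[0] == "GMvol:f3"
        assert all(a >= b for a, b in zip(ranking.scores, ranking.scores[1:]))

    def test_duplicate_feature_ties_broken_by_name(self):
        ids = ["a", "b", "c", "d"]
        labels = pd.Series(["Control", "Control", "PD", "PD"], index=ids)
        col = [0.0, 1.0, 5.0, 6.0]
        fm = self._fm({"GMvol:zz_copy": col, "GMvol:aa_orig": col,
                       "GMvol:noise": [0.3, -0.1, 0.2, 0.0]}, ids)
        ranking = rank_features(fm, labels)
        assert ranking.features[:2] == ["GMvol:aa_orig", "GMvol:zz_copy"]
        assert ranking.scores[0] == ranking.scores[1]

    def test_single_class_rejected(self):
        ids = ["a", "b", "c"]
        fm = self._fm({"GMvol:x": [1.0, 2.0, 3.0]}, ids)
        with pytest.raises(ValueError, match="2 classes"):
            rank_features(fm, pd.Series(["PD"] * 3, index=ids))

    def test_null_ranking_is_uniform_over_features(self):
        """With pure-noise features, each feature is equally likely on top."""
        n_feat, runs = 5, 200
        ids = [f"s{i}" for i in range(12)]
        labels = pd.Series(["Control"] * 6 + ["PD"] * 6, index=ids)
        cols = [f"GMvol:f{i}" for i in range(n_feat)]
        top = np.zeros(n_feat)
        for s in range(runs):
            rng = np.random.default_rng(1000 + s)
            fm = FeatureMatrix(pd.DataFrame(rng.normal(size=(12, n_feat)),
                                            index=ids, columns=cols))
            top[cols.index(rank_features(fm, labels).features[0])] += 1
        from scipy.stats import chisquare
        assert chisquare(top).pvalue > 0.01


class TestIncrementalSVM:
    def _split(self, seed=0, delta=6.0, n=8, p=4):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(2 * n)]
        labels = pd.Series(["Control"] * n + ["PD"] * n, index=ids)
        data = pd.DataFrame(rng.normal(size=(2 * n, p)), index=ids,
                            columns=[f"GMvol:f{i}" for i in range(p)])
        data.loc[labels == "PD", "GMvol:f0"] += delta
        test_ids = ids[:2] + ids[-2:]
        train_ids = [i for i in ids if i not in test_ids]
        fm = FeatureMatrix(data)
        return fm.rows(train_ids), fm.rows(test_ids), labels

    def test_separable_case_is_perfect_at_k1(self):
        train, test, labels = self._split()
        ranking = rank_features(train, labels)
        preds, _ = incremental_svm_accuracy(train, test, labels, ranking, k_max=1)
        assert (preds.loc[1] == labels[preds.columns]).all()

    def test_all_features_matches_direct_svm(self):
        train, test, labels = self._split(seed=3, delta=1.0)
        ranking = rank_features(train, labels)
        preds, weights = incremental_svm_accuracy(train, test, labels, ranking,
                                                  keep_weights=True)
        k_full = len(ranking.features)
        direct = SVC(kernel="linear", C=1.0)
        direct.fit(train.data[ranking.features], labels[train.subject_ids])
        np.testing.assert_array_equal(preds.loc[k_full],
                                      direct.predict(test.data[ranking.features]))
        assert set(weights) == set(range(1, k_full + 1))

    def test_k_max_clipped_with_warning(self, caplog):
        train, test, labels = self._split()
        ranking = rank_features(train, labels)
        with caplog.at_level("WARNING"):
            preds, _ = incremental_svm_accuracy(train, test, labels, ranking,
                                                k_max=99)
        assert preds.index.max() == len(ranking.features)
        assert "clipping" in caplog.text

    def test_permuted_labels_give_chance_accuracy(self):
        accs = []
        for s in range(50):
            rng = np.random.default_rng(s)
            train, test, labels = self._split(seed=s, delta=6.0)
            permuted = pd.Series(rng.permutation(labels.to_numpy()),
                                 index=labels.index)
            # re-permute until both classes appear in the training rows
            while permuted[train.subject_ids].nunique() < 2:
                permuted = pd.Series(rng.permutation(labels.to_numpy()),
                                     index=labels.index)
            ranking = rank_features(train, permuted)
            preds, _ = incremental_svm_accuracy(train, test, permuted, ranking,
                                                k_max=2)
            truth = permuted[preds.columns]
            accs.append((preds == truth).to_numpy().mean())
        assert abs(np.mean(accs) - 0.5) < 0.06


class TestLeaveTwoOut:
    def test_exhaustive_fold_count_19_vs_19(self, null_features):
        fm, labels = null_features(n_per_class=19, n_features=2, seed=0)
        curve = leave_two_out_cv(fm, labels, CVConfig(k_max=1))
        assert curve.n_folds == 361                      # 19 x 19 pairings
        assert curve.positive_class == "PD"

    def test_strong_effect_recovers_high_accuracy(self, null_features):
        fm, labels = null_features(n_per_class=8, n_features=20, seed=1)
        data = fm.data.copy()
        data.loc[labels == "PD", data.columns[:5]] += 3.0   # 3-sd shift
        curve = leave_two_out_cv(FeatureMatrix(data), labels,
                                 CVConfig(folds=30, seed=2, k_max=10))
        assert np.mean(curve.accuracy) > 0.90

    def test_fold_exchangeability_under_subject_reordering(self, null_features):
        fm, labels = null_features(n_per_class=4, n_features=4, seed=5)
        base = leave_two_out_cv(fm, labels, CVConfig(k_max=3))
        perm = list(np.random.default_rng(0).permutation(fm.subject_ids))
        shuffled = leave_two_out_cv(fm.rows(perm), labels.loc[perm],
                                    CVConfig(k_max=3))
        np.testing.assert_allclose(base.accuracy, shuffled.accuracy)

    def test_requires_three_per_class(self, null_features):
        fm, labels = null_features(n_per_class=2, n_features=3)
        with pytest.raises(ValueError, match="3 subjects"):
            leave_two_out_cv(fm, labels)


class TestIndependentValidation:
    def _effect_cohort(self, seed, n, effect, prefix):
        rng = np.random.default_rng(seed)
        ids = [f"{prefix}A{i}" for i in range(n)] + [f"{prefix}B{i}" for i in range(n)]
        labels = pd.Series(["Control"] * n + ["PD"] * n, index=ids)
        data = pd.DataFrame(rng.normal(size=(2 * n, 12)), index=ids,
                            columns=[f"GMvol:f{i:02d}" for i in range(12)])
        data.loc[labels == "PD", data.columns[:4]] += effect
        return FeatureMatrix(data), labels

    def test_same_generator_validation_close_to_cv(self):
        train, lt = self._effect_cohort(0, 10, 3.0, "t")
        val, lv = self._effect_cohort(1, 10, 3.0, "v")
        labels = pd.concat([lt, lv])
        cv = leave_two_out_cv(train, lt, CVConfig(folds=40, seed=0, k_max=8))
        iv = independent_validation(train, val, labels, CVConfig(k_max=8))
        assert abs(np.mean(cv.accuracy) - np.mean(iv.accuracy)) < 0.10

    def test_no_effect_in_validation_drops_to_chance(self):
        train, lt = self._effect_cohort(2, 10, 3.0, "t")
        val, lv = self._effect_cohort(3, 10, 0.0, "v")
        iv = independent_validation(train, val, pd.concat([lt, lv]),
                                    CVConfig(k_max=8))
        assert 0.25 < np.mean(iv.accuracy) < 0.75
        assert iv.balanced_accuracy is not None

    def test_overlapping_subjects_rejected(self):
        train, lt = self._effect_cohort(4, 5, 1.0, "t")
        with pytest.raises(ValueError, match="both cohorts"):
            independent_validation(train, train, lt)


def test_leakage_paper_mode_not_below_safe_mode_on_null_data():
    """Joint normalization/PCA (paper mode) cannot be less optimistic than
    the leakage-safe pipeline on null data, up to Monte-Carlo error."""
    gaps = []
    for s in range(10):
        rng = np.random.default_rng(2000 + s)
        ids = [f"A{i}" for i in range(8)] + [f"B{i}" for i in range(8)]
        labels = pd.Series(["Control"] * 8 + ["PD"] * 8, index=ids)
        vox = pd.DataFrame(rng.normal(size=(16, 24)), index=ids)
        safe = leave_two_out_cv(vox, labels,
                                CVConfig(method="pca", mode="safe", folds=12,
                                         seed=s, k_max=6))
        paper = leave_two_out_cv(vox, labels,
                                 CVConfig(method="pca", mode="paper", folds=12,
                                          seed=s, k_max=6))
        gaps.append(np.mean(paper.accuracy) - np.mean(safe.accuracy))
    gap = np.mean(gaps)
    mc_err = np.std(gaps, ddof=1) / np.sqrt(len(gaps))
    assert gap >= -2 * mc_err


def test_pair_label_positive_class_convention():
    assert pair_label("PSP-RS", "PD") == ("PD vs PSP-RS", "PD", "PSP-RS")
    assert pair_label("CBS", "Control") == ("Control vs CBS", "Control", "CBS")
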