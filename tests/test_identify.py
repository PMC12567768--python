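"""Longitudinal identification: splits, AUC, pairwise matrices, rankings."""

import numpy as np
import pandas as pd
import pytest

import eegdaae as E
from eegdaae.identify import (_trial_folds, crossval_select, feature_columns,
                              majority_vote_accuracy, make_classifier)

from conftest import gaussian_feature_table


class TestLongitudinalSplit:
    def test_split_is_by_session_and_disjoint(self):
        table = gaussian_feature_table(n_subjects=3, n_trials=4, seed=0)
        train, test = E.longitudinal_split(table)
        assert (train["session"] == 1).all()
        assert (test["session"] == 2).all()
        assert len(train) + len(test) == len(table)

    def test_study_scale_row_counts(self):
        """7 subjects x 55 trials x 9 segments split 385 x 9 rows per side."""
        table = gaussian_feature_table(n_subjects=7, n_trials=55, n_segments=9,
                                       n_features=2, seed=1)
        train, test = E.longitudinal_split(table)
        assert len(train) == len(test) == 385 * 9

    def test_missing_session_rejected(self):
        table = gaussian_feature_table(n_subjects=2, n_trials=3, seed=0)
        with pytest.raises(ValueError):
            E.longitudinal_split(table[table["session"] == 1])


class TestFitAndScore:
    def test_separable_classes_reach_perfect_auc(self):
        table = gaussian_feature_table(n_subjects=2, n_trials=8,
                                       separation=50.0, seed=2)
        train, test = E.longitudinal_split(table)
        assert E.fit_and_score(train, test, "knn") == 1.0

    def test_shuffled_labels_score_at_chance(self):
        """Permutation null: mean AUC over 20 label shuffles is ~0.5."""
        table = gaussian_feature_table(n_subjects=2, n_trials=8,
                                       separation=50.0, seed=3)
        train, test = E.longitudinal_split(table)
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(20):
            shuffled = train.copy()
            shuffled["subject"] = rng.permutation(shuffled["subject"].to_numpy())
            aucs.append(E.fit_and_score(shuffled, test, "knn"))
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_all_four_classifier_kinds_run(self):
        table = gaussian_feature_table(n_subjects=2, n_trials=5,
                                       separation=5.0, seed=4)
        train, test = E.longitudinal_split(table)
        for kind in E.CLASSIFIER_KINDS:
            assert 0.0 <= E.fit_and_score(train, test, kind, seed=0) <= 1.0

    def test_single_test_class_rejected(self):
        table = gaussian_feature_table(n_subjects=2, n_trials=4, seed=5)
        train, test = E.longitudinal_split(table)
        with pytest.raises(ValueError):
            E.fit_and_score(train, test[test["subject"] == "sb01"], "knn")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_classifier("qda")

    def test_leakage_guard_trips(self):
        table = gaussian_feature_table(n_subjects=2, n_trials=4, seed=6)
        train, test = E.longitudinal_split(table)
        contaminated = pd.concat([train, test.iloc[:3]])
        with pytest.raises(ValueError, match="leakage"):
            E.fit_and_score(contaminated, test, "knn")
        with pytest.raises(ValueError, match="leakage"):
            E.fit_and_score(train, train, "knn")


class TestCrossvalSelect:
    def test_single_point_grid_returned(self):
        table = gaussian_feature_table(n_subjects=2, n_trials=5, seed=7)
        train, _ = E.longitudinal_split(table)
        best = crossval_select(train, "knn", {"n_neighbors": [3]}, k_folds=2)
        assert best == {"n_neighbors": 3}

    def test_folds_partition_rows_grouped_by_trial(self):
        table = gaussian_feature_table(n_subjects=2, n_trials=10, n_segments=3, seed=8)
        train, _ = E.longitudinal_split(table)
        folds = _trial_folds(train, 5, seed=0)
        allidx = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(allidx, np.arange(len(train)))
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 3  # one trial group = 3 rows
        for f in folds:
            trials = train.iloc[f][["subject", "trial"]].apply(tuple, axis=1)
            others = train.drop(train.index[f])[["subject", "trial"]].apply(tuple, axis=1)
            assert not set(trials) & set(others)

    def test_selection_deterministic(self):
        table = gaussian_feature_table(n_subjects=2, n_trials=6, seed=9)
        train, _ = E.longitudinal_split(table)
        grid = {"n_neighbors": [3, 4, 5], "weights": ["uniform", "distance"]}
        a = crossval_select(train, "knn", grid, k_folds=3, seed=5)
        b = crossval_select(train, "knn", grid, k_folds=3, seed=5)
        assert a == b

    def test_empty_grid_rejected(self):
        table = gaussian_feature_table(n_subjects=2, n_trials=4, seed=10)
        train, _ = E.longitudinal_split(table)
        with pytest.raises(ValueError):
            crossval_select(train, "knn", {"n_neighbors": []})


class TestPairwise:
    def test_matrix_geometry(self):
        table = gaussian_feature_table(n_subjects=4, n_trials=4,
                                       separation=10.0, seed=11)
        mat = E.pairwise_matrix(table, "knn")
        assert mat.shape == (4, 4)
        assert mat.isna().to_numpy().diagonal().all()
        assert int(mat.notna().to_numpy().sum()) == 4 * 3  # n(n-1) symmetric cells
        pd.testing.assert_frame_equal(mat, mat.T)

    def test_separated_pair_identified(self):
        table = gaussian_feature_table(n_subjects=2, n_trials=8,
                                       separation=20.0, seed=12)
        mat = E.pairwise_matrix(table, "knn")
        assert mat.loc["sb01", "sb02"] >= 0.95

    def test_identical_distributions_score_at_chance(self):
        table = gaussian_feature_table(n_subjects=2, n_trials=10, n_segments=9,
                                       separation=0.0, seed=13)
        mat = E.pairwise_matrix(table, "knn")
        assert 0.4 <= mat.loc["sb01", "sb02"] <= 0.6

    def test_single_subject_rejected(self):
        table = gaussian_feature_table(n_subjects=2, n_trials=3, seed=14)
        with pytest.raises(ValueError):
            E.pairwise_matrix(table[table["subject"] == "sb01"], "knn")

    def test_degradation_monotone_in_session_drift(self):
        """Mean pairwise accuracy does not increase as session-2 drift grows."""
        means = []
        for drift in (0.0, 4.0, 12.0):
            table = gaussian_feature_table(n_subjects=3, n_trials=6,
                                           separation=3.0, drift=drift, seed=15)
            mat = E.pairwise_matrix(table, "knn")
            means.append(np.nanmean(mat.to_numpy(dtype=float)))
        assert means[0] >= means[1] >= means[2]


class TestIdentifiability:
    def make_matrix(self, values):
        subs = [f"sb{i:02d}" for i in range(1, len(values) + 1)]
        mat = pd.DataFrame(values, index=subs, columns=subs, dtype=float)
        np.fill_diagonal(mat.to_numpy(), np.nan)
        return mat

    def test_equal_accuracies_tie_broken_by_id(self):
        mat = self.make_matrix(np.full((3, 3), 0.8))
        scores, ranked = E.identifiability(mat)
        assert np.allclose(scores, 0.8)
        assert ranked == ["sb01", "sb02", "sb03"]

    def test_weak_subject_ranked_least_identifiable(self):
        v = np.full((4, 4), 1.0)
        v[2, :] = v[:, 2] = 0.5
        scores, ranked = E.identifiability(self.make_matrix(v))
        assert ranked[0] == "sb03"
        assert ((scores >= 0) & (scores <= 1)).all()


class TestDropAndRetrain:
    def test_drop_two_of_four(self):
        table = gaussian_feature_table(n_subjects=4, n_trials=5,
                                       separation=5.0, seed=16)
        out = E.drop_and_retrain(table, ["sb03", "sb04"], "knn")
        assert out["n_subjects"] == 2
        assert 0.0 <= out["auc"] <= 1.0

    def test_drop_none_matches_baseline(self):
        table = gaussian_feature_table(n_subjects=3, n_trials=5,
                                       separation=5.0, seed=17)
        train, test = E.longitudinal_split(table)
        baseline = E.fit_and_score(train, test, "knn")
        assert E.drop_and_retrain(table, [], "knn")["auc"] == baseline

    def test_overdropping_rejected(self):
        table = gaussian_feature_table(n_subjects=4, n_trials=3, seed=18)
        with pytest.raises(ValueError):
            E.drop_and_retrain(table, ["sb01", "sb02", "sb03"], "knn")


class TestMajorityVote:
    def test_vote_aggregates_to_trial_level(self):
        table = gaussian_feature_table(n_subjects=2, n_trials=6, n_segments=3,
                                       separation=10.0, seed=19)
        train, test = E.longitudinal_split(table)
        acc = majority_vote_accuracy(train, test, "knn")
        assert 0.0 <= acc <= 1.0
        assert acc >= 0.9  # widely separated clusters

    def test_feature_columns_detected(self):
        table = gaussian_feature_table(n_features=5, seed=20)
        assert feature_columns(table) == ["f0", "f1", "f2", "f3", "f4"]
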