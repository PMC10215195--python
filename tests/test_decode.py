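"""Subject-grouped cross-validated SVM: normalization, folds, leakage."""

import numpy as np
import pytest

from fosdecode import ClassifierConfig, FeatureMatrix, cross_validate, grouped_folds
from fosdecode.decode import zscore_fit_apply
from fosdecode.errors import DecodeError


class TestZscore:
    def test_two_point_column_population_convention(self):
        ztr, _ = zscore_fit_apply(np.array([[0.0], [2.0]]))
        np.testing.assert_allclose(ztr.ravel(), [-1.0, 1.0])

    def test_constant_column_zeroed(self):
        train = np.column_stack([np.ones(4), np.arange(4.0)])
        ztr, zte = zscore_fit_apply(train, train[:2])
        assert np.all(ztr[:, 0] == 0.0) and np.all(zte[:, 0] == 0.0)
        assert ztr[:, 1].std() == pytest.approx(1.0)

    def test_test_value_at_train_mean_maps_to_zero(self):
        train = np.array([[1.0], [3.0]])
        _, zte = zscore_fit_apply(train, np.array([[2.0]]))
        assert zte[0, 0] == 0.0

    def test_statistics_from_train_only(self):
        r = np.random.default_rng(0)
        train = r.standard_normal((50, 3))
        test = 100.0 + r.standard_normal((10, 3))
        ztr, zte = zscore_fit_apply(train, test)
        np.testing.assert_allclose(ztr.mean(0), 0.0, atol=1e-12)
        np.testing.assert_allclose(ztr.std(0), 1.0, atol=1e-12)
        assert zte.mean() > 50  # test offset survives: not normalized on itself


class TestGroupedFolds:
    def test_41_subjects_round_robin_sizes(self):
        subjects = np.repeat([f"s{i}" for i in range(41)], 3)
        folds = grouped_folds(subjects, 5, seed=0)
        sizes = sorted(
            len({s for s, f in zip(subjects, folds) if f == k}) for k in range(5)
        )
        assert sizes == [8, 8, 8, 8, 9]

    def test_subject_in_exactly_one_fold(self):
        subjects = np.repeat([f"s{i}" for i in range(11)], 7)
        folds = grouped_folds(subjects, 5, seed=3)
        for s in set(subjects):
            assert len(set(folds[subjects == s])) == 1

    def test_deterministic_for_seed(self):
        subjects = np.repeat([f"s{i}" for i in range(9)], 4)
        np.testing.assert_array_equal(
            grouped_folds(subjects, 5, seed=5), grouped_folds(subjects, 5, seed=5)
        )

    def test_too_few_subjects_raises(self):
        with pytest.raises(DecodeError, match="subjects"):
            grouped_folds(np.array(["a", "a", "b"]), 5)


def _gaussian_features(n=500, d=8, sep=4.0, n_subjects=10, seed=0):
    r = np.random.default_rng(seed)
    y = r.integers(0, 2, n)
    X = r.standard_normal((n, d))
    X[y == 1, 0] += sep
    subjects = np.array([f"s{i % n_subjects}" for i in range(n)])
    return FeatureMatrix(values=X, labels=y, subjects=subjects, meta={})


class TestCrossValidate:
    def test_separated_gaussians_high_accuracy(self):
        fm = _gaussian_features()
        preds = cross_validate(fm, ClassifierConfig(seed=0))
        assert preds.accuracy >= 0.95

    def test_shuffled_labels_chance_level(self):
        fm = _gaussian_features(n=2000, sep=0.0, seed=1)
        preds = cross_validate(fm, ClassifierConfig(seed=1))
        assert 0.45 <= preds.accuracy <= 0.55

    def test_no_test_subject_in_training_split(self):
        fm = _gaussian_features()
        preds = cross_validate(fm, ClassifierConfig(seed=2))
        for k in range(5):
            test_subj = set(preds.subjects[preds.fold == k])
            train_subj = set(preds.subjects[preds.fold != k])
            assert not (test_subj & train_subj)

    def test_deterministic(self):
        fm = _gaussian_features()
        a = cross_validate(fm, ClassifierConfig(seed=4))
        b = cross_validate(fm, ClassifierConfig(seed=4))
        np.testing.assert_array_equal(a.y_pred, b.y_pred)
        np.testing.assert_array_equal(a.score, b.score)
        np.testing.assert_array_equal(a.fold, b.fold)

    def test_fold_model_recomputable_from_out_of_fold_rows_only(self):
        # leakage guard: fold k's normalization and model must be functions
        # of non-k rows only — rebuild them independently and compare
        from sklearn.svm import SVC

        fm = _gaussian_features(seed=5)
        cfg = ClassifierConfig(seed=5)
        preds = cross_validate(fm, cfg)
        folds = grouped_folds(fm.subjects, cfg.n_folds, cfg.seed)
        np.testing.assert_array_equal(folds, preds.fold)
        for k in range(cfg.n_folds):
            test = folds == k
            Xtr, Xte = zscore_fit_apply(fm.values[~test], fm.values[test])
            clf = SVC(kernel="rbf", gamma=cfg.gamma / fm.values.shape[1], C=cfg.C)
            clf.fit(Xtr, fm.labels[~test])
            np.testing.assert_allclose(clf.decision_function(Xte), preds.score[test])
            np.testing.assert_array_equal(clf.predict(Xte), preds.y_pred[test])

    def test_single_class_training_split_rejected(self):
        r = np.random.default_rng(6)
        X = r.standard_normal((40, 4))
        subjects = np.repeat([f"s{i}" for i in range(5)], 8)
        y = (subjects == "s0").astype(int)  # one subject holds all positives
        fm = FeatureMatrix(values=X, labels=y, subjects=subjects, meta={})
        with pytest.raises(DecodeError, match="single class"):
            cross_validate(fm, ClassifierConfig(seed=0))

    def test_raw_gamma_convention_degenerates_at_high_dim(self):
        # documents why the normalized convention is the default: the
        # literal exp(-0.5 d^2) kernel at 128 z-scored features predicts
        # a single class
        fm = _gaussian_features(n=400, d=128, sep=4.0, seed=7)
        raw = cross_validate(fm, ClassifierConfig(seed=7, gamma_convention="raw"))
        norm = cross_validate(fm, ClassifierConfig(seed=7))
        assert len(set(raw.y_pred)) == 1
        assert norm.accuracy >= 0.9

    def test_youden_threshold_policy_runs(self):
        fm = _gaussian_features(seed=8)
        preds = cross_validate(fm, ClassifierConfig(seed=8, threshold="youden"))
        assert preds.accuracy >= 0.9

    def test_chance_level_across_seeds_within_binomial_band(self):
        # label-independent features over 20 seeds: mean accuracy inside the
        # 95% binomial band of a fair coin at the per-run row count
        n = 600
        accs = [
            cross_validate(
                _gaussian_features(n=n, sep=0.0, seed=100 + s),
                ClassifierConfig(seed=s),
            ).accuracy
            for s in range(20)
        ]
        half_width = 1.96 * np.sqrt(0.25 / n)
        assert abs(np.mean(accs) - 0.5) <= half_width
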