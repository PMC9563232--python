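"""Linear-SVM predictive model: LOSO evaluation, ROC metrics, bootstrap, RFE."""

import numpy as np
import pytest
from scipy import stats

from natfmri.predictive_model import (
    bootstrap_feature_test,
    confusion_and_roc,
    CVResult,
    fit_svm_loso,
    rfe_select,
)


def _clouds(n_subjects=7, per_subject=14, n_features=10, sep=10.0, seed=0):
    """Two far-separated Gaussian clouds, balanced within every subject."""
    rng = np.random.default_rng(seed)
    X, y, subj = [], [], []
    for s in range(n_subjects):
        for cls in (0, 1):
            n = per_subject // 2
            X.append(rng.normal(cls * sep, 1.0, size=(n, n_features)))
            y += [cls] * n
            subj += [s] * n
    return np.vstack(X), np.array(y), np.array(subj)


class TestLOSO:
    def test_separable_clouds_perfect_on_every_fold(self):
        X, y, subj = _clouds()
        cv = fit_svm_loso(X, y, subj)
        assert len(cv.y_pred) == 98  # 7 subjects x 14 samples
        assert set(cv.fold_ids) == set(range(7))
        for s in range(7):
            fold = cv.fold_ids == s
            assert fold.sum() == 14
            assert np.array_equal(cv.y_pred[fold], cv.y_true[fold])

    def test_each_sample_predicted_exactly_once(self):
        X, y, subj = _clouds(n_subjects=3, per_subject=4)
        cv = fit_svm_loso(X, y, subj)
        assert len(cv.y_pred) == len(y)
        for s in np.unique(subj):
            assert np.all(cv.fold_ids[subj == s] == s)

    def test_single_subject_rejected(self):
        X, y, subj = _clouds(n_subjects=1)
        with pytest.raises(ValueError, match="2 subjects"):
            fit_svm_loso(X, y, subj)

    def test_class_missing_from_training_fold_rejected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 4))
        y = np.array([0, 0, 0, 0, 1, 1])
        subj = np.array([0, 0, 1, 1, 2, 2])  # class 1 only in subject 2
        with pytest.raises(ValueError, match="missing a class"):
            fit_svm_loso(X, y, subj)

    def test_permuted_labels_near_chance(self):
        """Label permutation with pure-noise features: pooled accuracy falls in
        the 95% binomial band around 0.5 over repeats."""
        rng = np.random.default_rng(7)
        n_subjects, per_subject, n_feat = 5, 10, 500
        accs = []
        for _ in range(10):
            X = rng.normal(size=(n_subjects * per_subject, n_feat))
            # permute within subjects (the LOSO exchangeability blocks) so
            # training folds stay balanced and the binomial null applies
            y = np.concatenate(
                [rng.permutation(np.tile([0, 1], per_subject // 2))
                 for _ in range(n_subjects)]
            )
            subj = np.repeat(np.arange(n_subjects), per_subject)
            cv = fit_svm_loso(X, y, subj)
            accs.append(np.mean(cv.y_pred == cv.y_true))
        n_total = len(accs) * n_subjects * per_subject
        lo, hi = stats.binom.interval(0.95, n_total, 0.5)
        assert lo / n_total <= np.mean(accs) <= hi / n_total


class TestConfusionAndROC:
    @staticmethod
    def _cv_from(decisions, y_true):
        decisions = np.asarray(decisions, dtype=float)
        y_true = np.asarray(y_true)
        return CVResult(
            decision_values=decisions,
            y_pred=(decisions > 0).astype(int),
            y_true=y_true,
            fold_ids=np.zeros(len(y_true), dtype=int),
            fold_weights={},
            classes=(0, 1),
        )

    def test_identities_on_random_tables(self, rng):
        """S_N and S_P match direct arithmetic on every random confusion table."""
        for _ in range(1000):
            n = rng.integers(10, 60)
            y = rng.integers(0, 2, size=n)
            dec = rng.normal(size=n)
            if len(np.unique(y)) < 2:
                continue
            m = confusion_and_roc(self._cv_from(dec, y))
            TP = np.sum((y == 1) & (dec > 0))
            FN = np.sum((y == 1) & (dec <= 0))
            TN = np.sum((y == 0) & (dec <= 0))
            FP = np.sum((y == 0) & (dec > 0))
            assert (m.TP, m.FN, m.FP, m.TN) == (TP, FN, FP, TN)
            assert m.S_N == TP / (TP + FN)
            assert m.S_P == TN / (TN + FP)

    def test_perfect_classifier(self):
        y = np.array([0, 0, 1, 1])
        m = confusion_and_roc(self._cv_from([-2, -1, 1, 2], y))
        assert m.S_N == m.S_P == m.accuracy == m.auc == 1.0

    def test_worked_confusion_example(self, rng):
        dec = np.concatenate([np.ones(80), -np.ones(20), np.ones(18), -np.ones(82)])
        y = np.concatenate([np.ones(100, int), np.zeros(100, int)])
        m = confusion_and_roc(self._cv_from(dec, y))
        assert m.S_N == pytest.approx(0.80)
        assert m.S_P == pytest.approx(0.82)

    def test_auc_matches_pairwise_oracle(self, rng):
        """Trapezoid AUC equals the O(n^2) probability that a positive sample
        outranks a negative one (ties counted half)."""
        y = rng.integers(0, 2, size=200)
        dec = y + rng.normal(0, 0.8, size=200)
        m = confusion_and_roc(self._cv_from(dec, y))
        pos, neg = dec[y == 1], dec[y == 0]
        cmp_matrix = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
        assert m.auc == pytest.approx(cmp_matrix.mean(), abs=0.01)

    def test_roc_invariant_to_monotone_transform(self, rng):
        y = rng.integers(0, 2, size=100)
        dec = rng.normal(size=100)
        m1 = confusion_and_roc(self._cv_from(dec, y))
        m2 = confusion_and_roc(self._cv_from(np.exp(dec) - 1.0, y))
        assert np.allclose(m1.fpr, m2.fpr) and np.allclose(m1.tpr, m2.tpr)
        assert m1.auc == pytest.approx(m2.auc, abs=1e-12)
        assert np.all(np.diff(m1.tpr) >= 0) and np.all(np.diff(m1.fpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            confusion_and_roc(self._cv_from([1.0, 2.0], [1, 1]))


class TestBootstrap:
    def test_label_copy_feature_always_selected_positive(self, rng):
        y = np.tile([0, 1], 20)
        X = np.column_stack([2 * y - 1, rng.normal(size=(40, 20))])
        sig = bootstrap_feature_test(X, y, B=100, seed=1)
        assert sig.selected[0]
        assert sig.sign[0] == 1

    def test_same_seed_identical_selection(self, rng):
        X = rng.normal(size=(30, 50))
        y = np.tile([0, 1], 15)
        s1 = bootstrap_feature_test(X, y, B=100, seed=5)
        s2 = bootstrap_feature_test(X, y, B=100, seed=5)
        assert np.array_equal(s1.selected, s2.selected)
        assert np.array_equal(s1.statistic, s2.statistic)

    def test_small_B_rejected(self, rng):
        with pytest.raises(ValueError, match="B"):
            bootstrap_feature_test(rng.normal(size=(10, 5)), np.tile([0, 1], 5), B=50)


class TestRFE:
    def test_informative_features_survive(self, rng):
        y = np.tile([0, 1], 25)
        X = rng.normal(size=(50, 100)) * 0.1
        X[:, [13, 77]] += np.column_stack([2 * y - 1, 2 * y - 1])
        sig = rfe_select(X, y, n_keep=2)
        assert set(np.flatnonzero(sig.selected)) == {13, 77}

    def test_keep_all_is_identity(self, rng):
        X = rng.normal(size=(20, 30))
        y = np.tile([0, 1], 10)
        sig = rfe_select(X, y, n_keep=30)
        assert sig.selected.all()

    def test_final_step_truncates_to_n_keep(self, rng):
        X = rng.normal(size=(20, 97))
        y = np.tile([0, 1], 10)
        # 50% steps from 97 would jump past 7 without truncation
        sig = rfe_select(X, y, step_fraction=0.5, n_keep=7)
        assert sig.selected.sum() == 7

    def test_n_keep_bounds_checked(self, rng):
        X = rng.normal(size=(10, 5))
        y = np.tile([0, 1], 5)
        with pytest.raises(ValueError, match="n_keep"):
            rfe_select(X, y, n_keep=6)


class TestRecoveryEnrichment:
    def test_selected_voxels_enriched_in_planted_regions(self, small_dataset):
        """Both selection methods concentrate on planted regions
        (hypergeometric p < 0.01)."""
        from natfmri.spatial_activation import build_design, feature_matrix
        from natfmri.synthetic_data import block_design_timing

        cfg, atlas, mask, truth, runs = small_dataset
        onsets, durations = block_design_timing(cfg)
        design = build_design(onsets, durations, cfg.n_volumes, cfg.tr_seconds)
        X, y, subj, idxmap = feature_matrix(runs, design, mask)
        planted_flat = np.isin(atlas.labels, list(truth.spatial_regions))[mask]

        boot = bootstrap_feature_test(X, y, B=100, seed=3)
        rfe = rfe_select(X, y, n_keep=int(planted_flat.sum()))
        for sig in (boot, rfe):
            n_sel = int(sig.selected.sum())
            overlap = int((sig.selected & planted_flat).sum())
            p = stats.hypergeom.sf(
                overlap - 1, len(planted_flat), int(planted_flat.sum()), n_sel
            )
            assert p < 0.01, sig.method
            # signs follow the full-data weight direction on signal features
            assert np.all(np.isin(sig.sign[sig.selected], [-1, 1]))
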