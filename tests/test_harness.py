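import numpy as np
import pytest

import zebraldt as z
from zebraldt import harness
from zebraldt.harness import (
    CODING_A,
    CODING_B,
    ClassifierSpec,
    build_estimator,
    compute_metrics,
    dual_coding_run,
    fit_predict_cv,
    make_folds,
)


class TestMakeFolds:
    def test_72_sample_partition(self, default_matrix):
        folds = make_folds(default_matrix.labels, k=5, seed=1,
                           sample_ids=default_matrix.sample_ids)
        sizes = sorted(np.bincount(folds.folds)[1:], reverse=True)
        assert sizes == [15, 15, 14, 14, 14]
        # stratification: each fold's class ratio within 1 sample of 50/50
        for f in range(1, 6):
            labs = default_matrix.labels[folds.folds == f]
            n_ctrl = np.sum(labs == "control")
            assert abs(n_ctrl - len(labs) / 2) <= 0.5

    def test_seed_determinism(self, default_matrix):
        a = make_folds(default_matrix.labels, seed=9, sample_ids=default_matrix.sample_ids)
        b = make_folds(default_matrix.labels, seed=9, sample_ids=default_matrix.sample_ids)
        assert np.array_equal(a.folds, b.folds)

    def test_small_class_rejected(self):
        labels = ["a"] * 3 + ["b"] * 3
        with pytest.raises(ValueError):
            make_folds(labels, k=5)


class TestClassifierSpec:
    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("svm")

    @pytest.mark.parametrize("family", z.FAMILIES)
    def test_estimators_instantiate(self, family):
        est = build_estimator(ClassifierSpec(family), random_state=0)
        assert hasattr(est, "fit")

    def test_hyperparameter_override(self):
        spec = ClassifierSpec("rf", hyperparameters={"n_estimators": 5})
        assert spec.params()["n_estimators"] == 5


class TestFitPredictCV:
    @pytest.mark.parametrize("family", z.FAMILIES)
    def test_separable_clouds_perfect_accuracy(self, separable_matrix, family):
        folds = make_folds(separable_matrix.labels, seed=0,
                           sample_ids=separable_matrix.sample_ids)
        preds = dual_coding_run(separable_matrix, ClassifierSpec(family), folds)
        assert compute_metrics(preds).accuracy == 1.0

    def test_every_sample_predicted_once_per_coding(self, small_null_matrix):
        folds = make_folds(small_null_matrix.labels, seed=2,
                           sample_ids=small_null_matrix.sample_ids)
        preds = dual_coding_run(small_null_matrix, ClassifierSpec("glm"), folds)
        assert preds.codings == [CODING_A, CODING_B]
        truth, pred = preds.pooled()
        assert len(truth) == len(pred) == 2 * small_null_matrix.n_samples
        for coding in preds.codings:
            assert set(preds.predicted[coding]) <= set(preds.classes)

    def test_fold_mismatch_rejected(self, small_null_matrix, separable_matrix):
        folds = make_folds(separable_matrix.labels, seed=0,
                           sample_ids=separable_matrix.sample_ids)
        with pytest.raises(ValueError):
            fit_predict_cv(small_null_matrix, ClassifierSpec("glm"), folds)

    def test_coding_symmetry_of_pooled_accuracy(self, default_matrix):
        """Globally swapping the class names leaves pooled accuracy unchanged."""
        folds = make_folds(default_matrix.labels, seed=4,
                           sample_ids=default_matrix.sample_ids)
        acc = z.pooled_accuracy(default_matrix, ClassifierSpec("glm"), folds)
        swapped = default_matrix.relabel(
            np.where(default_matrix.labels == "control", "exposed", "control")
        )
        acc_swapped = z.pooled_accuracy(swapped, ClassifierSpec("glm"), folds)
        assert acc == pytest.approx(acc_swapped, abs=1e-12)


class _MemorizingStub:
    """Returns the training label for any row it saw during fit, 0.5 otherwise.

    Under leak-free cross-validation it cannot beat chance on noise data;
    any accuracy near 1.0 would prove test rows leaked into training.
    """

    def __init__(self):
        self.memory = {}

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        self.memory = {row.tobytes(): lab for row, lab in zip(X, y)}
        return self

    def predict_proba(self, X):
        out = np.empty((len(X), 2))
        for i, row in enumerate(X):
            lab = self.memory.get(row.tobytes())
            if lab is None:
                out[i] = [0.5, 0.5]
            else:
                out[i] = [1.0, 0.0] if lab == self.classes_[0] else [0.0, 1.0]
        return out


class TestNoLeakage:
    def test_stub_memorizer_scores_chance_under_cv(self, monkeypatch):
        """A perfect memorizer gets ~0.5 out-of-fold: test rows never leak."""
        matrix = z.generate_null_matrix(18, 25, seed=77)
        monkeypatch.setattr(harness, "build_estimator", lambda spec, random_state: _MemorizingStub())
        folds = make_folds(matrix.labels, seed=3, sample_ids=matrix.sample_ids)
        acc = z.pooled_accuracy(matrix, ClassifierSpec("glm"), folds)
        assert acc == pytest.approx(0.5, abs=1e-12)

    def test_stub_memorizer_is_perfect_when_leaked(self):
        """Sanity: trained and evaluated on the same rows, the stub is perfect."""
        matrix = z.generate_null_matrix(10, 5, seed=8)
        stub = _MemorizingStub().fit(matrix.features, matrix.labels)
        proba = stub.predict_proba(matrix.features)
        pred = stub.classes_[(proba[:, 1] > 0.5).astype(int)]
        assert np.all(pred == matrix.labels)


class TestComputeMetrics:
    @staticmethod
    def _preds(truth, predicted):
        truth = np.asarray(truth)
        return z.PredictionSet(
            sample_ids=tuple(f"s{i}" for i in range(len(truth))),
            true_labels=truth,
            predicted={"A": np.asarray(predicted)},
            folds=np.ones(len(truth), dtype=int),
            classes=("control", "exposed"),
        )

    def test_confusion_arithmetic(self):
        truth = ["exposed"] * 36 + ["control"] * 36
        pred = ["exposed"] * 30 + ["control"] * 6 + ["control"] * 30 + ["exposed"] * 6
        m = compute_metrics(self._preds(truth, pred))
        assert (m.tp, m.tn, m.fp, m.fn) == (30, 30, 6, 6)
        assert m.accuracy == pytest.approx(60 / 72)
        assert m.sensitivity == pytest.approx(30 / 36)
        assert m.ppv == pytest.approx(30 / 36)

    def test_all_correct(self):
        truth = ["exposed"] * 5 + ["control"] * 5
        m = compute_metrics(self._preds(truth, truth))
        for v in (m.accuracy, m.sensitivity, m.specificity, m.ppv, m.npv):
            assert v == 1.0

    def test_degenerate_all_positive_npv_missing(self):
        truth = ["exposed"] * 5 + ["control"] * 5
        pred = ["exposed"] * 10
        m = compute_metrics(self._preds(truth, pred))
        assert m.specificity == 0.0
        assert np.isnan(m.npv)

    def test_wald_interval_brackets_accuracy(self):
        truth = ["exposed"] * 20 + ["control"] * 20
        pred = ["exposed"] * 15 + ["control"] * 25
        m = compute_metrics(self._preds(truth, pred))
        assert m.accuracy_ci_low < m.accuracy < m.accuracy_ci_high
        assert 0.0 <= m.accuracy_ci_low and m.accuracy_ci_high <= 1.0
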