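"""Dual-coding, stratified fivefold cross-validated two-group classification.

Four classifier families are supported — ``glm`` (ridge-regularized
logistic regression), ``rf`` (random forest), ``gbm`` (gradient boosting)
and ``dl`` (feed-forward neural network) — each with fixed explicit
defaults.  Every comparison is run twice with the two class codes swapped
(coding A: first class = 1, second = 2; coding B reversed) to cancel any
algorithmic preference for a particular coded value, and the 2N out-of-fold
predictions from both coding runs are pooled into one confusion table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import isnan, nan, sqrt

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .containers import EXPOSED, FeatureMatrix

logger = logging.getLogger(__name__)

FAMILIES = ("glm", "rf", "gbm", "dl")

CODING_A = "A"  # first class (sorted order) coded 1, second coded 2
CODING_B = "B"  # reversed

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "glm": {"C": 1.0, "max_iter": 200},
    "rf": {"n_estimators": 50, "max_features": "sqrt", "max_depth": 20},
    "gbm": {"n_estimators": 50, "max_depth": 5, "learning_rate": 0.1},
    "dl": {"hidden_layer_sizes": (200, 200), "activation": "relu", "max_iter": 10},
}
#: Families whose inputs are standardized (fit on training folds only).
STANDARDIZED_FAMILIES = frozenset({"glm", "dl"})


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family plus its hyperparameters and preprocessing."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    preprocessing: str | None = None  # none | standardize; default per family

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.preprocessing not in (None, "none", "standardize"):
            raise ValueError("preprocessing must be 'none' or 'standardize'")

    @property
    def standardize(self) -> bool:
        if self.preprocessing is None:
            return self.family in STANDARDIZED_FAMILIES
        return self.preprocessing == "standardize"

    def params(self) -> dict:
        return {**DEFAULT_HYPERPARAMETERS[self.family], **self.hyperparameters}


def build_estimator(spec: ClassifierSpec, random_state: int):
    """Instantiate the sklearn estimator (with scaler where applicable)."""
    p = spec.params()
    if spec.family == "glm":
        model = LogisticRegression(penalty="l2", solver="lbfgs", **p)
    elif spec.family == "rf":
        model = RandomForestClassifier(random_state=random_state, **p)
    elif spec.family == "gbm":
        model = GradientBoostingClassifier(random_state=random_state, **p)
    else:
        model = MLPClassifier(random_state=random_state, **p)
    if spec.standardize:
        return Pipeline([("scale", StandardScaler()), ("model", model)])
    return model


@dataclass(frozen=True)
class FoldAssignment:
    """Stratified partition of samples into k cross-validation folds."""

    sample_ids: tuple[str, ...]
    folds: np.ndarray  # fold index per sample, values in 1..k
    k: int
    seed: int

    def indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.flatnonzero(self.folds == fold)
        train = np.flatnonzero(self.folds != fold)
        return train, test


def make_folds(labels, k: int = 5, seed: int = 0,
               sample_ids: list[str] | None = None) -> FoldAssignment:
    """Stratified k-fold assignment, deterministic under the seed.

    Every class must have at least k members so each fold's class ratio
    stays within one sample of the global ratio.
    """
    labels = np.asarray(labels).astype(str)
    ids = tuple(sample_ids) if sample_ids is not None else tuple(
        f"s{i:04d}" for i in range(len(labels))
    )
    classes, counts = np.unique(labels, return_counts=True)
    too_small = classes[counts < k]
    if too_small.size:
        raise ValueError(
            f"class(es) {too_small.tolist()} have fewer than k={k} samples"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(labels), dtype=int)
    for fold_idx, (_, test) in enumerate(skf.split(np.zeros((len(labels), 1)), labels), start=1):
        folds[test] = fold_idx
    return FoldAssignment(sample_ids=ids, folds=folds, k=k, seed=seed)


@dataclass
class PredictionSet:
    """Out-of-fold predictions for one comparison, per coding run.

    ``predicted[coding]`` holds each sample's predicted label in the
    original label space; every sample is predicted exactly once per coding
    run, always by a model not trained on it.
    """

    sample_ids: tuple[str, ...]
    true_labels: np.ndarray
    predicted: dict[str, np.ndarray]
    folds: np.ndarray
    classes: tuple[str, str]

    @property
    def codings(self) -> list[str]:
        return sorted(self.predicted)

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """True and predicted labels pooled over all coding runs (2N pairs)."""
        truth = np.concatenate([self.true_labels for _ in self.codings])
        pred = np.concatenate([self.predicted[c] for c in self.codings])
        return truth, pred


def _coding_map(classes: tuple[str, str], coding: str) -> dict[str, int]:
    a, b = classes
    return {a: 1, b: 2} if coding == CODING_A else {a: 2, b: 1}


def fit_predict_cv(
    matrix: FeatureMatrix,
    spec: ClassifierSpec,
    folds: FoldAssignment,
    coding: str = CODING_A,
) -> PredictionSet:
    """One coding run of k-fold cross-validation.

    Classes are mapped to numeric codes per the coding, a fresh estimator is
    fit on each training split (scaler included, so no statistic leaks from
    test folds), and the held-out samples are labeled by thresholding the
    predicted probability of code 2 at 0.5 — ties go to the class coded 1.
    """
    classes = matrix.require_two_groups()
    if tuple(folds.sample_ids) != tuple(matrix.sample_ids):
        raise ValueError("fold assignment does not match the matrix samples")
    code_of = _coding_map(classes, coding)
    label_of = {v: k for k, v in code_of.items()}
    y = np.array([code_of[str(lab)] for lab in matrix.labels])
    X = matrix.features

    predicted = np.empty(matrix.n_samples, dtype=object)
    for fold in range(1, folds.k + 1):
        train, test = folds.indices(fold)
        seed = int(
            np.random.SeedSequence(
                [folds.seed, 0 if coding == CODING_A else 1, fold]
            ).generate_state(1)[0]
            % (2**31)
        )
        est = build_estimator(spec, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                est.fit(X[train], y[train])
                proba = est.predict_proba(X[test])
                p2 = proba[:, list(est.classes_).index(2)]
            except Exception as exc:  # pragma: no cover - defensive fallback
                logger.warning(
                    "family %s fold %d failed (%s); falling back to majority class",
                    spec.family, fold, exc,
                )
                majority = 1 if np.sum(y[train] == 1) >= np.sum(y[train] == 2) else 2
                p2 = np.full(len(test), 1.0 if majority == 2 else 0.0)
        codes = np.where(p2 > 0.5, 2, 1)  # tie (p = 0.5) -> class coded 1
        for idx, code in zip(test, codes):
            predicted[idx] = label_of[int(code)]

    return PredictionSet(
        sample_ids=tuple(matrix.sample_ids),
        true_labels=matrix.labels.astype(str),
        predicted={coding: predicted.astype(str)},
        folds=folds.folds.copy(),
        classes=classes,
    )


def dual_coding_run(
    matrix: FeatureMatrix, spec: ClassifierSpec, folds: FoldAssignment
) -> PredictionSet:
    """Both coding runs on the same folds, predictions mapped back and retained."""
    run_a = fit_predict_cv(matrix, spec, folds, CODING_A)
    run_b = fit_predict_cv(matrix, spec, folds, CODING_B)
    return PredictionSet(
        sample_ids=run_a.sample_ids,
        true_labels=run_a.true_labels,
        predicted={**run_a.predicted, **run_b.predicted},
        folds=run_a.folds,
        classes=run_a.classes,
    )


@dataclass(frozen=True)
class PerformanceMetrics:
    """Confusion counts and derived rates, pooled over coding runs.

    The exposed group is the positive class.  Ratios with a zero
    denominator are reported as NaN (missing), never as zero.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy_ci_low: float
    accuracy_ci_high: float

    @property
    def n_predictions(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy_ci_low": self.accuracy_ci_low,
            "accuracy_ci_high": self.accuracy_ci_high,
        }


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else nan


def compute_metrics(
    preds: PredictionSet, positive_label: str | None = None
) -> PerformanceMetrics:
    """Pool the coding runs into one confusion table and derive the five rates.

    ``positive_label`` defaults to ``"exposed"`` when present, otherwise the
    lexicographically larger class.  The accuracy interval is a Wald
    binomial 95% CI on the pooled prediction count.
    """
    truth, pred = preds.pooled()
    if positive_label is None:
        positive_label = EXPOSED if EXPOSED in preds.classes else preds.classes[1]
    t_pos = truth == positive_label
    p_pos = pred == positive_label
    tp = int(np.sum(t_pos & p_pos))
    tn = int(np.sum(~t_pos & ~p_pos))
    fp = int(np.sum(~t_pos & p_pos))
    fn = int(np.sum(t_pos & ~p_pos))
    n = tp + tn + fp + fn
    acc = (tp + tn) / n
    half = 1.96 * sqrt(acc * (1 - acc) / n)
    return PerformanceMetrics(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=acc,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        accuracy_ci_low=max(0.0, acc - half),
        accuracy_ci_high=min(1.0, acc + half),
    )


def pooled_accuracy(
    matrix: FeatureMatrix, spec: ClassifierSpec, folds: FoldAssignment
) -> float:
    """Convenience: pooled dual-coding cross-validated accuracy."""
    return compute_metrics(dual_coding_run(matrix, spec, folds)).accuracy
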