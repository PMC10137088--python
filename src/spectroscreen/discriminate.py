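"""LDA / SVM classification under repeated stratified cross-validation.

The design mirrors a small-cohort screening study: samples are split
into stratified folds (class proportions preserved to within one
sample), each fold serves as the test set exactly once per repeat, and
the whole procedure is repeated with re-shuffled folds.  Test
predictions are pooled into confusion counts within each repeat;
sensitivity, specificity and accuracy are then averaged over repeats.

Features are the preprocessed absorbance values at the retained
wavenumbers, standardized with train-fold statistics only (no leakage).
The SVM defaults to a linear kernel with unit cost.  LDA defaults to the
plain pooled-covariance discriminant, whose empirical covariance is
ill-conditioned when features far outnumber samples — the erratic
small-sample behavior typical of applied spectral studies; a Ledoit-Wolf
shrinkage covariance is available via ``lda_shrinkage="auto"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import UndefinedMetricError, ValidationError
from .spectra_io import POSITIVE_LABEL, SpectrumSet


@dataclass
class CVConfig:
    """Cross-validation and classifier settings."""

    n_folds: int = 10
    n_repeats: int = 3
    seed: int = 0
    algorithm: str = "SVM"  # or "LDA"
    svm_kernel: str = "linear"  # or "rbf"
    svm_cost: float = 1.0
    lda_shrinkage: str = "none"  # or "auto"
    balanced: bool = False  # optional class reweighting (off by default)

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")
        if self.algorithm not in ("SVM", "LDA"):
            raise ValidationError("algorithm must be 'SVM' or 'LDA'")
        if self.svm_kernel not in ("linear", "rbf"):
            raise ValidationError("svm_kernel must be 'linear' or 'rbf'")
        if self.svm_cost <= 0:
            raise ValidationError("svm_cost must be positive")
        if self.lda_shrinkage not in ("auto", "none"):
            raise ValidationError("lda_shrinkage must be 'auto' or 'none'")


@dataclass
class CVResult:
    """Fold assignments, per-execution confusion counts and summary metrics."""

    fold_assignments: list[np.ndarray]  # one int array per repeat
    per_execution: list[dict]  # repeat, fold, TP, FN, TN, FP
    confusion_per_repeat: list[dict]  # pooled within repeat
    sensitivity_mean: float
    sensitivity_sd: float
    specificity_mean: float
    specificity_sd: float
    accuracy_mean: float
    accuracy_sd: float
    repeat_seeds: list[int]
    config: CVConfig = field(repr=False, default=None)

    def summary(self) -> dict:
        return {
            "algorithm": self.config.algorithm if self.config else None,
            "sensitivity": self.sensitivity_mean,
            "sensitivity_sd": self.sensitivity_sd,
            "specificity": self.specificity_mean,
            "specificity_sd": self.specificity_sd,
            "accuracy": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "repeat_seeds": self.repeat_seeds,
        }


def metrics_from_confusion(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) from pooled confusion counts."""
    for c in (tp, fn, tn, fp):
        if c < 0:
            raise ValidationError("confusion counts must be non-negative")
    if tp + fn == 0:
        raise UndefinedMetricError("no positives: sensitivity undefined")
    if tn + fp == 0:
        raise UndefinedMetricError("no negatives: specificity undefined")
    total = tp + fn + tn + fp
    return tp / (tp + fn), tn / (tn + fp), (tp + tn) / total


def make_folds(labels, n_folds: int, seed: int) -> np.ndarray:
    """Stratified fold assignment: returns the test-fold index per sample.

    Per-fold class counts differ from exact proportionality by at most
    one sample; the assignment is deterministic given ``seed``.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("need both classes to stratify")
    if n_folds == y.size:
        # leave-one-out: singleton folds satisfy the proportionality
        # bound trivially; order shuffled for seed-consistency
        rng = np.random.default_rng(seed)
        return rng.permutation(y.size)
    if counts.min() < n_folds:
        raise ValidationError(
            f"minority class has {counts.min()} members < {n_folds} folds; "
            f"use n_folds <= {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seed) % 2**31)
    assignment = np.empty(y.size, dtype=int)
    for k, (_, test_idx) in enumerate(skf.split(np.zeros((y.size, 1)), y)):
        assignment[test_idx] = k
    return assignment


def _make_estimator(config: CVConfig) -> Pipeline:
    cw = "balanced" if config.balanced else None
    if config.algorithm == "SVM":
        clf = SVC(kernel=config.svm_kernel, C=config.svm_cost, class_weight=cw)
    else:
        shrink = "auto" if config.lda_shrinkage == "auto" else None
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrink)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def fit_predict(X_train, y_train, X_test, config: CVConfig) -> np.ndarray:
    """Fit the configured classifier on the train fold and label the test fold."""
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise ValidationError("training fold holds a single class")
    est = _make_estimator(config)
    est.fit(np.asarray(X_train, float), y_train)
    return est.predict(np.asarray(X_test, float))


def _resolve_xy(data, labels):
    if isinstance(data, SpectrumSet):
        X = data.to_matrix()
        y = data.labels()
        if any(g is None for g in y):
            raise ValidationError("every spectrum needs a group label")
    else:
        X = np.asarray(data, float)
        y = np.asarray(labels)
    return X, y


def cross_validate(data, config: CVConfig, labels=None) -> CVResult:
    """Repeated stratified k-fold cross-validation.

    ``data`` is a labelled SpectrumSet (features = absorbance matrix) or
    a plain feature matrix with ``labels``.  One master seed spawns one
    fold-shuffling seed per repeat; the full result is reproducible from
    the config alone.
    """
    X, y = _resolve_xy(data, labels)
    pos = y == POSITIVE_LABEL if y.dtype.kind in "OUS" else y.astype(bool)

    ss = np.random.SeedSequence(int(config.seed))
    repeat_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(config.n_repeats)]

    fold_assignments: list[np.ndarray] = []
    per_execution: list[dict] = []
    confusion_per_repeat: list[dict] = []
    sens_r, spec_r, acc_r = [], [], []
    for r, rseed in enumerate(repeat_seeds):
        folds = make_folds(y, config.n_folds, rseed)
        fold_assignments.append(folds)
        pooled = {"TP": 0, "FN": 0, "TN": 0, "FP": 0}
        for k in range(config.n_folds):
            test = folds == k
            pred = fit_predict(X[~test], y[~test], X[test], config)
            pred_pos = pred == POSITIVE_LABEL if y.dtype.kind in "OUS" else pred.astype(bool)
            cell = {
                "repeat": r,
                "fold": k,
                "TP": int(np.sum(pred_pos & pos[test])),
                "FN": int(np.sum(~pred_pos & pos[test])),
                "TN": int(np.sum(~pred_pos & ~pos[test])),
                "FP": int(np.sum(pred_pos & ~pos[test])),
            }
            per_execution.append(cell)
            for key in pooled:
                pooled[key] += cell[key]
        confusion_per_repeat.append(pooled)
        se, sp, ac = metrics_from_confusion(
            pooled["TP"], pooled["FN"], pooled["TN"], pooled["FP"]
        )
        sens_r.append(se)
        spec_r.append(sp)
        acc_r.append(ac)

    return CVResult(
        fold_assignments=fold_assignments,
        per_execution=per_execution,
        confusion_per_repeat=confusion_per_repeat,
        sensitivity_mean=float(np.mean(sens_r)),
        sensitivity_sd=float(np.std(sens_r, ddof=1)) if config.n_repeats > 1 else 0.0,
        specificity_mean=float(np.mean(spec_r)),
        specificity_sd=float(np.std(spec_r, ddof=1)) if config.n_repeats > 1 else 0.0,
        accuracy_mean=float(np.mean(acc_r)),
        accuracy_sd=float(np.std(acc_r, ddof=1)) if config.n_repeats > 1 else 0.0,
        repeat_seeds=repeat_seeds,
        config=config,
    )
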