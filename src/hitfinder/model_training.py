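"""Balanced classifier training with grid search and 10-fold cross-validation.

Two model families are trained on fingerprint bit-vectors: a random forest
(classic ensemble) and a multilayer perceptron (small neural network).
Bioactivity corpora are typically inactive-heavy, so the majority class is
randomly undersampled to the minority size before training.  Hyperparameters
are chosen by exhaustive grid search scored by mean cross-validated AUC:

* RF grid: ``n_estimators`` in {50, 100, 200}, ``max_depth`` in {4, 6, 10, 12};
* MLP grid: ``hidden_layer_sizes`` in {(50, 50, 50), (50, 50), (50,)},
  ``activation`` in {tanh, relu}, ``alpha`` in {0.01, 0.0001}.

Evaluation reports seven metrics per fold — AUC, precision, recall,
specificity, F1, geometric mean and the index of balanced accuracy (IBA):

    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 * precision * recall / (precision + recall)
    G-mean      = sqrt(recall * specificity)
    IBA_alpha   = (1 + alpha * (recall - specificity)) * recall * specificity

with ``alpha = 0.1`` by default.  Confusion-based metrics use a 0.5
probability threshold.  Undersampling happens once, before cross-validation,
with the run seed; this is simple and matches common practice but means folds
are drawn from the balanced set (a known mild optimism for the CV estimate).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .compound_curation import LabeledCompound
from .vectorization import ConfigError, FingerprintMatrix, FingerprintSpec

logger = logging.getLogger(__name__)

ModelKind = Literal["rf", "mlp"]

RF_GRID: dict[str, list] = {
    "n_estimators": [50, 100, 200],
    "max_depth": [4, 6, 10, 12],
}
MLP_GRID: dict[str, list] = {
    "hidden_layer_sizes": [(50, 50, 50), (50, 50), (50,)],
    "activation": ["tanh", "relu"],
    "alpha": [0.01, 0.0001],
}

# MLP fits in the grid are capped; separable fingerprint data converges well
# before this and stragglers are handled by the convergence-warning filter.
MLP_MAX_ITER = 300


@dataclass(frozen=True)
class TrainingConfig:
    models: tuple[ModelKind, ...] = ("rf", "mlp")
    rf_grid: dict = field(default_factory=lambda: dict(RF_GRID))
    mlp_grid: dict = field(default_factory=lambda: dict(MLP_GRID))
    n_folds: int = 10
    seed: int = 0
    iba_alpha: float = 0.1

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if not self.rf_grid or not self.mlp_grid:
            raise ConfigError("hyperparameter grids must be non-empty")

    def grid_for(self, kind: ModelKind) -> dict:
        return self.rf_grid if kind == "rf" else self.mlp_grid


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("confusion counts must not all be zero")


@dataclass(frozen=True)
class MetricsReport:
    auc: float
    precision: float
    recall: float
    specificity: float
    f1: float
    geometric_mean: float
    iba: float
    iba_alpha: float = 0.1
    divide_by_zero_flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "geometric_mean": self.geometric_mean,
            "iba": self.iba,
        }


@dataclass
class TrainedClassifier:
    """A fitted model plus its grid choice, CV metrics and provenance."""

    kind: ModelKind
    chosen_hyperparameters: dict
    cv_metrics: list[MetricsReport]
    estimator: object
    fingerprint_spec: FingerprintSpec = field(default_factory=FingerprintSpec)
    seed: int = 0

    @property
    def mean_cv_auc(self) -> float:
        return float(np.mean([m.auc for m in self.cv_metrics]))

    def mean_metrics(self) -> dict:
        keys = ["auc", "precision", "recall", "specificity", "f1", "geometric_mean", "iba"]
        return {k: float(np.mean([m.to_dict()[k] for m in self.cv_metrics])) for k in keys}

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.estimator, path)
        sidecar = {
            "kind": self.kind,
            "chosen_hyperparameters": _jsonable(self.chosen_hyperparameters),
            "fingerprint_spec": self.fingerprint_spec.to_dict(),
            "seed": self.seed,
            "mean_cv_metrics": self.mean_metrics(),
        }
        with open(path.with_suffix(path.suffix + ".json"), "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        path = Path(path)
        estimator = joblib.load(path)
        with open(path.with_suffix(path.suffix + ".json"), encoding="utf-8") as fh:
            meta = json.load(fh)
        params = meta["chosen_hyperparameters"]
        if "hidden_layer_sizes" in params:
            params["hidden_layer_sizes"] = tuple(params["hidden_layer_sizes"])
        return cls(
            kind=meta["kind"],
            chosen_hyperparameters=params,
            cv_metrics=[],
            estimator=estimator,
            fingerprint_spec=FingerprintSpec.from_dict(meta["fingerprint_spec"]),
            seed=int(meta["seed"]),
        )


def _jsonable(params: dict) -> dict:
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in params.items()}


# ---------------------------------------------------------------------------
# Undersampling
# ---------------------------------------------------------------------------

def undersample(labeled: Sequence[LabeledCompound], seed: int) -> list[LabeledCompound]:
    """Randomly downsample the majority class to the minority class size.

    Selection is without replacement and deterministic for a given seed; the
    minority class is kept untouched.  Output preserves input order.
    """
    actives = [i for i, c in enumerate(labeled) if c.label == "active"]
    inactives = [i for i, c in enumerate(labeled) if c.label == "inactive"]
    if not actives or not inactives:
        raise ValueError(
            f"undersampling needs both classes (got {len(actives)} active, "
            f"{len(inactives)} inactive)"
        )
    minority, majority = (actives, inactives) if len(actives) <= len(inactives) else (inactives, actives)
    rng = np.random.default_rng(seed)
    kept_majority = set(rng.choice(majority, size=len(minority), replace=False).tolist())
    kept = set(minority) | kept_majority
    logger.info(
        "undersampled majority class %d -> %d (minority %d)",
        len(majority), len(minority), len(minority),
    )
    return [c for i, c in enumerate(labeled) if i in kept]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def compute_metrics(
    counts: ConfusionCounts,
    iba_alpha: float = 0.1,
    auc: float = float("nan"),
) -> MetricsReport:
    """Evaluate the seven-metric report from confusion counts.

    Undefined ratios (zero denominators) are reported as 0 and flagged.
    """
    flags: list[str] = []

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    precision = _ratio(counts.tp, counts.tp + counts.fp, "precision")
    recall = _ratio(counts.tp, counts.tp + counts.fn, "recall")
    specificity = _ratio(counts.tn, counts.tn + counts.fp, "specificity")
    if precision + recall == 0:
        flags.append("f1")
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    gmean = float(np.sqrt(recall * specificity))
    iba = (1.0 + iba_alpha * (recall - specificity)) * recall * specificity
    return MetricsReport(
        auc=auc,
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        geometric_mean=gmean,
        iba=iba,
        iba_alpha=iba_alpha,
        divide_by_zero_flags=tuple(flags),
    )


def auc_from_curve(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """ROC AUC by trapezoidal integration of the curve."""
    return float(np.trapezoid(tpr, fpr))


# ---------------------------------------------------------------------------
# Model construction and cross-validation
# ---------------------------------------------------------------------------

def build_estimator(kind: ModelKind, params: dict, seed: int):
    if kind == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if kind == "mlp":
        return MLPClassifier(random_state=seed, max_iter=MLP_MAX_ITER, **params)
    raise ConfigError(f"unknown model kind {kind!r}")


def _check_folds(labels: np.ndarray, n_folds: int, seed: int, max_tries: int = 5) -> StratifiedKFold:
    """Seeded stratified folds; reseed (shifted) if any fold is single-class."""
    y = np.asarray(labels)
    for attempt in range(max_tries):
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + attempt)
        ok = True
        for _, test_idx in cv.split(np.zeros((len(y), 1)), y):
            if len(np.unique(y[test_idx])) < 2:
                ok = False
                break
        if ok:
            if attempt:
                logger.warning("re-drew folds %d time(s) to avoid single-class folds", attempt)
            return cv
    raise ValueError("could not build stratified folds with both classes present")


def cross_validate(
    features: FingerprintMatrix | np.ndarray,
    labels: Sequence[int],
    kind: ModelKind,
    config: TrainingConfig,
    params: dict | None = None,
) -> tuple[list[MetricsReport], list[dict]]:
    """Per-fold metric reports and ROC curves for one hyperparameter setting.

    Folds are stratified with the run seed; the ROC is the (FPR, TPR) curve of
    the fold's predicted probabilities with AUC by trapezoidal integration;
    confusion-based metrics use a 0.5 probability threshold.
    """
    X = features.bits if isinstance(features, FingerprintMatrix) else np.asarray(features)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels are not row-aligned")
    params = params or _default_params(kind, config)
    cv = _check_folds(y, config.n_folds, config.seed)
    reports: list[MetricsReport] = []
    curves: list[dict] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for fold, (train_idx, test_idx) in enumerate(cv.split(X, y)):
            est = build_estimator(kind, params, seed=config.seed + fold)
            est.fit(X[train_idx], y[train_idx])
            prob = est.predict_proba(X[test_idx])[:, 1]
            fpr, tpr, _ = roc_curve(y[test_idx], prob)
            pred = (prob >= 0.5).astype(int)
            truth = y[test_idx]
            counts = ConfusionCounts(
                tp=int(np.sum((pred == 1) & (truth == 1))),
                fp=int(np.sum((pred == 1) & (truth == 0))),
                tn=int(np.sum((pred == 0) & (truth == 0))),
                fn=int(np.sum((pred == 0) & (truth == 1))),
            )
            reports.append(compute_metrics(counts, config.iba_alpha, auc=auc_from_curve(fpr, tpr)))
            curves.append({"fold": fold, "fpr": fpr.tolist(), "tpr": tpr.tolist()})
    return reports, curves


def _default_params(kind: ModelKind, config: TrainingConfig) -> dict:
    grid = config.grid_for(kind)
    return {k: v[0] for k, v in grid.items()}


def train_model(
    features: FingerprintMatrix | np.ndarray,
    labels: Sequence[int],
    kind: ModelKind,
    config: TrainingConfig,
) -> TrainedClassifier:
    """Exhaustive grid search (mean CV AUC) + refit on all balanced data.

    The returned classifier carries per-fold metric reports for the winning
    hyperparameters and the fingerprint spec of the training features (used to
    refuse scoring a library vectorized under a different spec).
    """
    X = features.bits if isinstance(features, FingerprintMatrix) else np.asarray(features)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(X, axis=0)) == 1:
        logger.warning("degenerate features: all rows identical; training continues")
    cv = _check_folds(y, config.n_folds, config.seed)
    base = build_estimator(kind, _default_params(kind, config), seed=config.seed)
    search = GridSearchCV(
        base, param_grid=config.grid_for(kind), scoring="roc_auc", cv=cv, n_jobs=1, refit=True
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        search.fit(X, y)
    best_params = dict(search.best_params_)
    logger.info("%s grid search: best %s (mean CV AUC %.4f)", kind, best_params, search.best_score_)
    reports, _curves = cross_validate(features, labels, kind, config, params=best_params)
    spec = features.spec if isinstance(features, FingerprintMatrix) else FingerprintSpec()
    return TrainedClassifier(
        kind=kind,
        chosen_hyperparameters=best_params,
        cv_metrics=reports,
        estimator=search.best_estimator_,
        fingerprint_spec=spec,
        seed=config.seed,
    )


def metrics_table(clf: TrainedClassifier) -> "np.ndarray | object":
    """Per-fold + mean metric table (pandas) for one trained model."""
    import pandas as pd

    rows = [dict(fold=i, **m.to_dict()) for i, m in enumerate(clf.cv_metrics)]
    rows.append(dict(fold="mean", **clf.mean_metrics()))
    return pd.DataFrame(rows)
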