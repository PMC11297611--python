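"""Repeated stratified k-fold cross-validation, metrics, bootstrap CIs.

With 48 patients a single train/test split is far too noisy, so the
pipeline pools out-of-fold predictions from a repeated stratified 4-fold
scheme and computes the five classification metrics (precision,
sensitivity, F1, accuracy, AUC) on the pooled predictions. 95% confidence
intervals come from a cluster bootstrap over patients: a resample draws
patients with replacement and keeps all of a drawn patient's repetitions
together, respecting the patient as the sampling unit without refitting.

AUC is the Mann–Whitney statistic with midranks on the signed decision
scores (ties contribute 1/2), so constant scores give exactly 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from . import shap_engine, svm_classifier
from .shap_engine import KernelShapConfig
from .svm_classifier import SVMHyperparams
from .synthetic_ehr import Cohort

__all__ = [
    "FoldAssignment",
    "MetricSet",
    "MetricCI",
    "OOFPredictions",
    "METRIC_NAMES",
    "stratified_kfold",
    "repeated_cv_predict",
    "compute_metrics",
    "auc_midrank",
    "bootstrap_ci",
    "compute_metric_cis",
]

METRIC_NAMES = ("precision", "sensitivity", "f1", "accuracy", "auc")


@dataclass
class FoldAssignment:
    """Fold index per patient for each repetition (repeats x n_patients)."""

    assignments: np.ndarray
    k: int
    repeats: int
    seed: int

    def fold_indices(self, rep: int, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_idx, test_idx) for one repetition/fold."""
        mask = self.assignments[rep] == fold
        return np.flatnonzero(~mask), np.flatnonzero(mask)


@dataclass(frozen=True)
class MetricSet:
    precision: float
    sensitivity: float
    f1: float
    accuracy: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


@dataclass(frozen=True)
class MetricCI:
    """Point estimate with 95% percentile bootstrap bounds."""

    point: float
    lower: float
    upper: float
    rounds: int = 200

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


@dataclass
class OOFPredictions:
    """Pooled held-out predictions: one row per (patient, repetition)."""

    patient_idx: np.ndarray
    repetition: np.ndarray
    fold: np.ndarray
    score: np.ndarray
    pred: np.ndarray
    true: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.patient_idx)
        for name in ("repetition", "fold", "score", "pred", "true"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        pairs = set(zip(self.patient_idx.tolist(), self.repetition.tolist()))
        if len(pairs) != n:
            raise ValueError("duplicate (patient, repetition) pair in predictions")

    def __len__(self) -> int:
        return len(self.patient_idx)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_idx": self.patient_idx,
                "repetition": self.repetition,
                "fold": self.fold,
                "score": self.score,
                "pred": self.pred,
                "true": self.true,
            }
        )

    def take(self, row_idx: np.ndarray) -> "OOFPredictions":
        o = OOFPredictions.__new__(OOFPredictions)
        o.patient_idx = self.patient_idx[row_idx]
        o.repetition = self.repetition[row_idx]
        o.fold = self.fold[row_idx]
        o.score = self.score[row_idx]
        o.pred = self.pred[row_idx]
        o.true = self.true[row_idx]
        return o


def _derived_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def stratified_kfold(labels, k: int = 4, repeats: int = 5, seed: int = 0) -> FoldAssignment:
    """Stratified fold assignment; repetitions use distinct derived seeds.

    Per-fold class counts differ by at most one from perfect stratification
    (delegated to scikit-learn's StratifiedKFold with shuffling).
    """
    y = np.asarray(labels, int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"each class needs >= k={k} members, got counts {counts.tolist()}"
        )
    rep_seeds = _derived_seeds(seed, repeats)
    assignments = np.empty((repeats, len(y)), int)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(rep_seeds[r]))
        for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
            assignments[r, test_idx] = fold
    return FoldAssignment(assignments, k, repeats, seed)


def repeated_cv_predict(
    cohort: Cohort,
    feature_subset: Sequence[str],
    h: SVMHyperparams,
    folds: FoldAssignment,
    shap_cfg: KernelShapConfig | None = None,
) -> tuple[OOFPredictions, np.ndarray | None]:
    """Out-of-fold decision scores (and optional held-out SHAP) per repetition.

    For every repetition and fold the SVM is fitted on the training rows
    restricted to ``feature_subset``, the held-out rows are scored, and —
    when ``shap_cfg`` is given — Kernel SHAP is computed for each held-out
    row against a deterministic subsample of that fold's training rows.
    Returns predictions pooled over repetitions plus the SHAP matrix whose
    rows align with the prediction rows.
    """
    subset = list(feature_subset)
    if not subset:
        raise ValueError("feature_subset must be non-empty")
    X = cohort.subset_features(subset).astype(float)
    y = cohort.labels
    n = len(y)

    rows_pat, rows_rep, rows_fold = [], [], []
    rows_score, rows_true = [], []
    phi_blocks: list[np.ndarray] = []
    bg_seeds = _derived_seeds(shap_cfg.seed if shap_cfg else 0, folds.repeats * folds.k)

    for r in range(folds.repeats):
        for f in range(folds.k):
            train_idx, test_idx = folds.fold_indices(r, f)
            y_train = y[train_idx]
            if len(np.unique(y_train)) < 2:
                raise ValueError(
                    f"training fold is single-class (repetition {r}, fold {f})"
                )
            model = svm_classifier.fit(X[train_idx], y_train, h, feature_names=subset)
            scores = model.decision_scores(X[test_idx])
            rows_pat.append(test_idx)
            rows_rep.append(np.full(len(test_idx), r))
            rows_fold.append(np.full(len(test_idx), f))
            rows_score.append(scores)
            rows_true.append(y[test_idx])
            if shap_cfg is not None:
                bg_rng = np.random.default_rng(int(bg_seeds[r * folds.k + f]))
                size = min(shap_cfg.background_size, len(train_idx))
                bg_rows = train_idx[bg_rng.choice(len(train_idx), size, replace=False)]
                phi, _ = shap_engine.shap_matrix(
                    model.decision_scores, X[test_idx], X[bg_rows], shap_cfg
                )
                phi_blocks.append(phi)

    oof = OOFPredictions(
        patient_idx=np.concatenate(rows_pat),
        repetition=np.concatenate(rows_rep),
        fold=np.concatenate(rows_fold),
        score=np.concatenate(rows_score),
        pred=(np.concatenate(rows_score) > 0).astype(int),
        true=np.concatenate(rows_true),
    )
    phi_matrix = np.vstack(phi_blocks) if phi_blocks else None
    return oof, phi_matrix


def auc_midrank(scores, true) -> float:
    """AUC as the Mann–Whitney statistic with midranks (ties count 1/2)."""
    scores = np.asarray(scores, float)
    true = np.asarray(true, int)
    n1 = int(true.sum())
    n0 = len(true) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(scores)  # midranks
    return float((ranks[true == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def compute_metrics(oof: OOFPredictions) -> MetricSet:
    """The five pooled metrics from out-of-fold predictions."""
    true, pred = oof.true, oof.pred
    if len(np.unique(true)) < 2:
        raise ValueError("metrics require both classes among the true labels")
    tp = int(((pred == 1) & (true == 1)).sum())
    fp = int(((pred == 1) & (true == 0)).sum())
    fn = int(((pred == 0) & (true == 1)).sum())
    tn = int(((pred == 0) & (true == 0)).sum())
    if tp + fp == 0:
        warnings.warn("no predicted positives: precision defined as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    sensitivity = tp / (tp + fn)
    accuracy = (tp + tn) / len(true)
    denom = precision + sensitivity
    f1 = 2 * precision * sensitivity / denom if denom > 0 else 0.0
    return MetricSet(precision, sensitivity, f1, accuracy, auc_midrank(oof.score, true))


def _metric_value(oof: OOFPredictions, metric: str) -> float:
    return getattr(compute_metrics(oof), metric)


def bootstrap_ci(
    oof: OOFPredictions, metric: str, rounds: int = 200, seed: int = 0
) -> MetricCI:
    """95% percentile CI from a cluster bootstrap over patients.

    Each round resamples patients with replacement and keeps every
    repetition of a drawn patient; rounds whose resample lacks a class are
    redrawn (at most 1000 attempts per round).
    """
    if rounds < 2:
        raise ValueError("rounds must be >= 2")
    if metric not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRIC_NAMES}")
    rng = np.random.default_rng(seed)
    patients = np.unique(oof.patient_idx)
    by_patient = {p: np.flatnonzero(oof.patient_idx == p) for p in patients}
    point = _metric_value(oof, metric)
    vals = np.empty(rounds)
    for b in range(rounds):
        for _attempt in range(1000):
            draw = rng.choice(patients, size=len(patients), replace=True)
            row_idx = np.concatenate([by_patient[p] for p in draw])
            sub = oof.take(row_idx)
            if len(np.unique(sub.true)) == 2:
                break
        else:
            raise RuntimeError(
                "bootstrap resamples persistently single-class; cohort too small"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vals[b] = _metric_value(sub, metric)
    lower, upper = np.percentile(vals, [2.5, 97.5])
    return MetricCI(point, float(lower), float(upper), rounds)


def compute_metric_cis(
    oof: OOFPredictions, rounds: int = 200, seed: int = 0
) -> dict[str, MetricCI]:
    """Bootstrap CIs for all five metrics from one shared resampling stream.

    Uses a single set of patient resamples for all metrics so the CIs are
    computed on identical resamples (and 5x fewer metric passes).
    """
    if rounds < 2:
        raise ValueError("rounds must be >= 2")
    rng = np.random.default_rng(seed)
    patients = np.unique(oof.patient_idx)
    by_patient = {p: np.flatnonzero(oof.patient_idx == p) for p in patients}
    points = compute_metrics(oof).as_dict()
    vals = {m: np.empty(rounds) for m in METRIC_NAMES}
    for b in range(rounds):
        for _attempt in range(1000):
            draw = rng.choice(patients, size=len(patients), replace=True)
            row_idx = np.concatenate([by_patient[p] for p in draw])
            sub = oof.take(row_idx)
            if len(np.unique(sub.true)) == 2:
                break
        else:
            raise RuntimeError(
                "bootstrap resamples persistently single-class; cohort too small"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ms = compute_metrics(sub)
        for m in METRIC_NAMES:
            vals[m][b] = getattr(ms, m)
    out = {}
    for m in METRIC_NAMES:
        lower, upper = np.percentile(vals[m], [2.5, 97.5])
        out[m] = MetricCI(points[m], float(lower), float(upper), rounds)
    return out
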