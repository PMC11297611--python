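"""Gaussian-kernel soft-margin SVM behind a minimal fit/score contract.

The classifier the selection loop trains and explains. A thin, contract-
checked wrapper over scikit-learn's SVC with the RBF kernel
K(x, x') = exp(-gamma * ||x - x'||^2): trained models remember their
feature names and refuse to score matrices whose columns differ, so a
feature-elimination loop cannot silently misalign columns.

The study this emulates did not report C, gamma, class weighting, or any
probability calibration, so the defaults are the widely used C = 1 and
gamma = "scale" (1 / (n_features * Var(X))), with no class weighting (the
cohort is nearly balanced); every pipeline output records the resolved
values in its provenance block. AUC and SHAP both consume the signed
decision margin rather than calibrated probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

__all__ = ["SVMHyperparams", "TrainedClassifier", "fit", "decision_scores"]


@dataclass(frozen=True)
class SVMHyperparams:
    C: float = 1.0
    gamma: float | str = "scale"
    class_weight: str = "none"  # "none" | "balanced"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError(f"C must be > 0, got {self.C}")
        if isinstance(self.gamma, str):
            if self.gamma != "scale":
                raise ValueError(f"gamma must be positive or 'scale', got {self.gamma!r}")
        elif self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.class_weight not in ("none", "balanced"):
            raise ValueError(f"class_weight must be 'none' or 'balanced', got {self.class_weight!r}")


@dataclass
class TrainedClassifier:
    """Fitted SVC plus the training feature-name contract."""

    _svc: SVC
    feature_names: tuple[str, ...]
    hyperparams: SVMHyperparams

    @property
    def resolved_gamma(self) -> float:
        return float(self._svc._gamma)

    @property
    def n_support_vectors(self) -> int:
        return int(self._svc.n_support_.sum())

    def decision_scores(self, X, feature_names=None) -> np.ndarray:
        return decision_scores(self, X, feature_names)

    def predict(self, X, feature_names=None) -> np.ndarray:
        return (self.decision_scores(X, feature_names) > 0).astype(int)


def fit(X, y, h: SVMHyperparams = SVMHyperparams(), feature_names=None) -> TrainedClassifier:
    """Train the RBF-kernel SVM. Deterministic given (X, y, h)."""
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be 2-D with at least one feature column")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("y must contain both classes")
    if feature_names is None:
        feature_names = tuple(f"f{j}" for j in range(X.shape[1]))
    feature_names = tuple(feature_names)
    if len(feature_names) != X.shape[1]:
        raise ValueError("feature_names length must match X columns")
    svc = SVC(
        kernel="rbf",
        C=h.C,
        gamma=h.gamma,
        class_weight=None if h.class_weight == "none" else h.class_weight,
        random_state=h.seed,
    )
    svc.fit(X, y)
    return TrainedClassifier(svc, feature_names, h)


def decision_scores(m: TrainedClassifier, X, feature_names=None) -> np.ndarray:
    """Signed margin per row; predicted label is 1 iff the score is > 0."""
    X = np.asarray(X, float)
    if feature_names is not None and tuple(feature_names) != m.feature_names:
        got, want = set(feature_names), set(m.feature_names)
        raise ValueError(
            "feature columns differ from training: "
            f"unexpected={sorted(got - want)}, missing={sorted(want - got)}, "
            f"order_ok={tuple(feature_names) == m.feature_names}"
        )
    if X.shape[1] != len(m.feature_names):
        raise ValueError(
            f"X has {X.shape[1]} columns, model trained on {len(m.feature_names)}"
        )
    return np.asarray(m._svc.decision_function(X), float)
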