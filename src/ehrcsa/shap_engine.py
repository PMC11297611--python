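"""Model-agnostic Shapley attribution: exact enumeration and Kernel SHAP.

A prediction f(x) is decomposed into per-feature contributions phi_i (SHAP
values) plus a base value phi_0, the model's mean score over a background
sample. Features in a coalition S take the explained instance's values;
features outside S are marginalized *interventionally* over the background
rows, which is well-defined for binary problem-list features:

    v(S) = mean_b f(x_S, b_{not S}),   phi_0 = v(empty),  phi sums to v(F) - v(empty).

Two estimators are provided:

``exact_shapley``
    Full 2^M coalition enumeration of the classical Shapley formula
    phi_i = sum_{S not containing i} |S|!(M-|S|-1)!/M! * (v(S+i) - v(S)).
    The oracle; refuses M > 15.

``kernel_shap``
    The weighted-least-squares estimator: regress v(S) on coalition
    indicator vectors under the Shapley kernel weight
    pi(s) = (M-1) / (C(M,s) * s * (M-s)), with the efficiency constraint
    sum(phi) = v(F) - v(empty) eliminated exactly. With every proper
    non-empty coalition enumerated this recovers the exact values; with a
    sampled coalition budget it is the estimator used inside the selection
    loop. Budgets below M+2 leave the system underdetermined; the
    minimum-norm least-squares solution is returned (deterministic, and
    efficiency still holds exactly by construction).

The positive direction of phi follows the model score: for the SVM here, a
positive SHAP value pushes the decision toward the case class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ValueFunction",
    "ShapVector",
    "KernelShapConfig",
    "shapley_kernel_weight",
    "coalition_value",
    "exact_shapley",
    "kernel_shap",
    "shap_matrix",
    "aggregate_importance",
]

_EXACT_MAX_M = 15


@dataclass
class ValueFunction:
    """Coalition value v(S) for explaining one instance of one model.

    ``model_fn`` maps an (n, M) array to n real scores. ``x`` is the
    explained row; ``background`` the reference rows used to marginalize
    absent features.
    """

    model_fn: Callable[[np.ndarray], np.ndarray]
    x: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float).ravel()
        self.background = np.atleast_2d(np.asarray(self.background, float))
        if self.background.shape[0] == 0:
            raise ValueError("background must contain at least one row")
        if self.background.shape[1] != self.x.size:
            raise ValueError("background columns must match x length")

    @property
    def n_features(self) -> int:
        return self.x.size


@dataclass
class ShapVector:
    """Per-feature attributions phi plus the base value phi_0 = v(empty)."""

    phi: np.ndarray
    base_value: float
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, float).ravel()
        if self.feature_names is not None:
            self.feature_names = tuple(self.feature_names)
            if len(self.feature_names) != self.phi.size:
                raise ValueError("feature_names length must match phi")

    @property
    def total(self) -> float:
        """base_value + sum(phi): should equal v(F) (efficiency axiom)."""
        return float(self.base_value + self.phi.sum())


@dataclass(frozen=True)
class KernelShapConfig:
    """Coalition sampling budget and background for the WLS estimator.

    ``n_coalitions="auto"`` resolves to 2M + 512 capped at full enumeration
    (2^M - 2 proper non-empty coalitions); ``"all"`` forces enumeration.
    """

    n_coalitions: int | str = "auto"
    background_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_coalitions, str):
            if self.n_coalitions not in ("auto", "all"):
                raise ValueError("n_coalitions must be an int, 'auto' or 'all'")
        elif self.n_coalitions < 1:
            raise ValueError("n_coalitions must be >= 1")
        if self.background_size < 1:
            raise ValueError("background_size must be >= 1")

    def resolve_budget(self, m: int) -> int | None:
        """Coalition count for M features; None means full enumeration."""
        full = 2**m - 2 if m < 63 else None
        if self.n_coalitions == "all":
            if full is None:
                raise ValueError("full enumeration infeasible for this many features")
            return None
        budget = 2 * m + 512 if self.n_coalitions == "auto" else int(self.n_coalitions)
        if full is not None and budget >= full:
            return None
        return budget


def shapley_kernel_weight(m: int, s: int) -> float:
    """pi(s) = (M-1) / (C(M,s) * s * (M-s)) for 0 < s < M."""
    if not 0 < s < m:
        raise ValueError("coalition size must be strictly between 0 and M")
    return (m - 1) / (math.comb(m, s) * s * (m - s))


def coalition_value(vf: ValueFunction, S: Sequence[int]) -> float:
    """v(S): mean model score with features in S set to x, others to background."""
    idx = np.asarray(list(S), int)
    if idx.size and (idx.min() < 0 or idx.max() >= vf.n_features):
        raise ValueError("coalition indices out of range")
    synth = vf.background.copy()
    if idx.size:
        synth[:, idx] = vf.x[idx]
    return float(np.mean(vf.model_fn(synth)))


def _values_for_masks(vf: ValueFunction, masks: np.ndarray, chunk: int = 4096) -> np.ndarray:
    """v(S) for each boolean mask row, batching model calls."""
    k, m = masks.shape
    bg = vf.background
    nb = bg.shape[0]
    out = np.empty(k)
    for start in range(0, k, chunk):
        blk = masks[start : start + chunk]
        # (kb, nb, M): background rows with masked features overwritten by x
        synth = np.where(blk[:, None, :], vf.x[None, None, :], bg[None, :, :])
        scores = np.asarray(vf.model_fn(synth.reshape(-1, m)), float)
        out[start : start + chunk] = scores.reshape(len(blk), nb).mean(axis=1)
    return out


def _all_masks(m: int) -> np.ndarray:
    ints = np.arange(2**m, dtype=np.int64)
    return ((ints[:, None] >> np.arange(m)) & 1).astype(bool)


def exact_shapley(vf: ValueFunction, feature_names=None) -> ShapVector:
    """Exact Shapley values by full 2^M coalition enumeration (M <= 15)."""
    m = vf.n_features
    if m > _EXACT_MAX_M:
        raise ValueError(
            f"exact enumeration supports at most {_EXACT_MAX_M} features "
            f"(got {m}); use kernel_shap"
        )
    masks = _all_masks(m)
    v = _values_for_masks(vf, masks)
    sizes = masks.sum(axis=1)
    # w[s] = s! (M-1-s)! / M!
    w = np.array(
        [math.factorial(s) * math.factorial(m - 1 - s) / math.factorial(m) for s in range(m)]
    )
    ints = np.arange(2**m, dtype=np.int64)
    phi = np.empty(m)
    for i in range(m):
        without = (ints >> i) & 1 == 0
        s_wo = sizes[without]
        phi[i] = float(np.sum(w[s_wo] * (v[ints[without] | (1 << i)] - v[without])))
    return ShapVector(phi, base_value=float(v[0]), feature_names=feature_names)


def _enumerate_proper_masks(m: int) -> tuple[np.ndarray, np.ndarray]:
    masks = _all_masks(m)
    sizes = masks.sum(axis=1)
    keep = (sizes > 0) & (sizes < m)
    masks, sizes = masks[keep], sizes[keep]
    weights = np.array([shapley_kernel_weight(m, int(s)) for s in sizes])
    return masks, weights


def sample_coalitions(
    m: int, budget: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified coalition sample of size ``budget`` with WLS weights.

    Coalition sizes are visited in complementary pairs (1, M-1), (2, M-2), ...
    in order of decreasing Shapley-kernel mass. A size whose subsets all fit
    in the remaining budget is enumerated completely (weight pi(s) each);
    the remaining budget is split across the leftover sizes in proportion to
    their total kernel mass, sampling subsets uniformly and assigning each
    sampled coalition weight mass_s / count_s so every size stratum carries
    its correct total weight.
    """
    sizes = list(range(1, m))
    mass = {s: shapley_kernel_weight(m, s) * math.comb(m, s) for s in sizes}
    masks_parts: list[np.ndarray] = []
    weights_parts: list[np.ndarray] = []
    remaining = budget
    pending: list[int] = []
    # complementary pairs, outermost (largest mass) first
    order: list[list[int]] = []
    for s in range(1, m // 2 + 1):
        pair = [s] if s == m - s else [s, m - s]
        order.append(pair)
    for pair in order:
        count = sum(math.comb(m, s) for s in pair)
        if count <= remaining - len(pending):  # keep >=1 slot per pending size
            for s in pair:
                sub = _masks_of_size(m, s)
                masks_parts.append(sub)
                weights_parts.append(np.full(len(sub), shapley_kernel_weight(m, s)))
            remaining -= count
        else:
            pending.extend(pair)
    if pending and remaining > 0:
        total_mass = sum(mass[s] for s in pending)
        alloc = _largest_remainder(
            [mass[s] / total_mass * remaining for s in pending], remaining
        )
        for s, cnt in zip(pending, alloc):
            if cnt == 0:
                continue
            sub = np.zeros((cnt, m), bool)
            for r in range(cnt):
                sub[r, rng.permutation(m)[:s]] = True
            masks_parts.append(sub)
            weights_parts.append(np.full(cnt, mass[s] / cnt))
    if not masks_parts:
        raise ValueError("coalition budget too small to sample anything")
    return np.concatenate(masks_parts), np.concatenate(weights_parts)


def _masks_of_size(m: int, s: int) -> np.ndarray:
    from itertools import combinations

    combs = list(combinations(range(m), s))
    out = np.zeros((len(combs), m), bool)
    for r, c in enumerate(combs):
        out[r, list(c)] = True
    return out


def _largest_remainder(targets: list[float], total: int) -> list[int]:
    floors = [int(t) for t in targets]
    short = total - sum(floors)
    rema = sorted(range(len(targets)), key=lambda i: targets[i] - floors[i], reverse=True)
    for i in rema[:short]:
        floors[i] += 1
    return floors


def _solve_constrained_wls(
    masks: np.ndarray, weights: np.ndarray, v: np.ndarray, v0: float, vf_val: float
) -> np.ndarray:
    """WLS over coalition indicators with sum(phi) = v(F) - v(0) exact.

    The constraint is eliminated through the last feature; underdetermined
    systems get the minimum-norm solution from lstsq.
    """
    k, m = masks.shape
    total = vf_val - v0
    if m == 1:
        return np.array([total])
    z = masks.astype(float)
    a = z[:, :-1] - z[:, -1:]
    b = v - v0 - z[:, -1] * total
    sw = np.sqrt(weights)
    theta, *_ = np.linalg.lstsq(a * sw[:, None], b * sw, rcond=None)
    phi = np.empty(m)
    phi[:-1] = theta
    phi[-1] = total - theta.sum()
    return phi


def kernel_shap(
    vf: ValueFunction, cfg: KernelShapConfig = KernelShapConfig(), feature_names=None
) -> ShapVector:
    """Kernel SHAP estimate for one instance; deterministic given cfg.seed."""
    m = vf.n_features
    if m < 1:
        raise ValueError("at least one feature required")
    v0 = coalition_value(vf, [])
    v_full = coalition_value(vf, range(m))
    if m == 1:
        return ShapVector(np.array([v_full - v0]), v0, feature_names)
    budget = cfg.resolve_budget(m)
    if budget is None:
        masks, weights = _enumerate_proper_masks(m)
    else:
        rng = np.random.default_rng(cfg.seed)
        masks, weights = sample_coalitions(m, budget, rng)
    v = _values_for_masks(vf, masks)
    phi = _solve_constrained_wls(masks, weights, v, v0, v_full)
    return ShapVector(phi, v0, feature_names)


def shap_matrix(
    model_fn: Callable[[np.ndarray], np.ndarray],
    X_explain: np.ndarray,
    background: np.ndarray,
    cfg: KernelShapConfig = KernelShapConfig(),
    feature_names=None,
) -> tuple[np.ndarray, float]:
    """Kernel SHAP for every row of ``X_explain`` against one background.

    Row i of the returned matrix equals ``kernel_shap`` on that row with the
    same config: the coalition masks depend only on (M, budget, seed), so
    they are shared across rows and the weighted design is factored once.
    Returns ``(Phi, base_value)`` with Phi aligned to X_explain rows.
    """
    X_explain = np.atleast_2d(np.asarray(X_explain, float))
    background = np.atleast_2d(np.asarray(background, float))
    n, m = X_explain.shape
    if n == 0:
        raise ValueError("X_explain must contain at least one row")
    if background.shape[0] == 0:
        raise ValueError("background must contain at least one row")
    v0 = float(np.mean(model_fn(background)))
    v_full = np.asarray(model_fn(X_explain), float)
    if m == 1:
        return (v_full - v0)[:, None], v0
    budget = cfg.resolve_budget(m)
    if budget is None:
        masks, weights = _enumerate_proper_masks(m)
    else:
        rng = np.random.default_rng(cfg.seed)
        masks, weights = sample_coalitions(m, budget, rng)

    # Factor the weighted constrained design once; each row only changes b.
    z = masks.astype(float)
    a = z[:, :-1] - z[:, -1:]
    sw = np.sqrt(weights)
    pinv = np.linalg.pinv(a * sw[:, None])

    phi_out = np.empty((n, m))
    for i in range(n):
        vf = ValueFunction(model_fn, X_explain[i], background)
        v = _values_for_masks(vf, masks)
        total = v_full[i] - v0
        b = v - v0 - z[:, -1] * total
        theta = pinv @ (b * sw)
        phi_out[i, :-1] = theta
        phi_out[i, -1] = total - theta.sum()
    return phi_out, v0


def aggregate_importance(phi_matrix: np.ndarray) -> np.ndarray:
    """Per-feature mean |phi| over instances (the bar-plot statistic)."""
    phi_matrix = np.atleast_2d(np.asarray(phi_matrix, float))
    if phi_matrix.shape[0] == 0 or phi_matrix.size == 0:
        raise ValueError("phi matrix must contain at least one instance")
    return np.abs(phi_matrix).mean(axis=0)
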