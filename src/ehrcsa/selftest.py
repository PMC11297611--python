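"""Built-in sanity suite: oracle equivalence and planted-structure recovery.

A fast, self-contained check that the Kernel SHAP estimator agrees with
exact enumeration on small random games and that the elimination loop can
recover features planted with a strong case/control prevalence contrast.
Used by ``ehrcsa selftest``; the full versions live in the test suite.
"""

from __future__ import annotations

import numpy as np

from .csa import CSAConfig, run_csa, select_optimal
from .evaluation import METRIC_NAMES
from .shap_engine import KernelShapConfig, ValueFunction, exact_shapley, kernel_shap
from .svm_classifier import SVMHyperparams
from .synthetic_ehr import CohortConfig, InformativeFeature, generate_cohort


def random_game(rng: np.random.Generator, m: int):
    """A random quadratic model with random instance and background rows."""
    w = rng.normal(size=m)
    pairs = [(rng.integers(m), rng.integers(m)) for _ in range(m)]
    coefs = rng.normal(size=len(pairs))

    def model(X):
        X = np.atleast_2d(X)
        out = X @ w
        for (i, j), c in zip(pairs, coefs):
            out = out + c * X[:, i] * X[:, j]
        return out

    x = rng.integers(0, 2, m).astype(float)
    background = rng.integers(0, 2, (4, m)).astype(float)
    return ValueFunction(model, x, background)


def oracle_equivalence(seed: int, n_games: int = 20, max_m: int = 8) -> float:
    """Max abs deviation of full-enumeration kernel SHAP from exact values."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_games):
        m = int(rng.integers(2, max_m + 1))
        vf = random_game(rng, m)
        exact = exact_shapley(vf)
        kern = kernel_shap(vf, KernelShapConfig(n_coalitions="all", seed=seed))
        worst = max(worst, float(np.abs(exact.phi - kern.phi).max()))
    return worst


def planted_recovery(seed: int):
    """Run a small planted cohort through CSA; return (found, planted)."""
    planted = [
        InformativeFeature(f"planted_{i}", 0.75, 0.05) for i in range(3)
    ]
    cfg = CohortConfig(
        n_cases=24, n_controls=24, n_features=12,
        informative_features=planted, seed=seed,
    )
    cohort = generate_cohort(cfg)
    csa_cfg = CSAConfig(
        svm=SVMHyperparams(),
        cv_repeats=1,
        shap=KernelShapConfig(n_coalitions=64, background_size=8),
        bootstrap_rounds=20,
        seed=seed,
    )
    trace = run_csa(cohort, csa_cfg)
    selected, _ = select_optimal(trace)
    names = {f.name for f in planted}
    return len(names & set(selected)), len(names)


def run_selftest(seed: int = 0, echo=print) -> bool:
    ok = True
    dev = oracle_equivalence(seed)
    echo(f"oracle equivalence: max |kernel - exact| = {dev:.2e} (tolerance 1e-5)")
    if dev >= 1e-5:
        ok = False
    found, total = planted_recovery(seed)
    echo(f"planted recovery: {found}/{total} planted features selected (need >= {total - 1})")
    if found < total - 1:
        ok = False
    return ok
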