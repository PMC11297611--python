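"""Contribution selection: SHAP-ranked backward elimination of features.

Starting from the full feature set, each iteration (i) cross-validates the
RBF-SVM on the current set, (ii) pools Kernel SHAP attributions of the
held-out predictions, and (iii) drops the feature with the smallest mean
|phi|, down to ``min_features``. The trace of per-size metrics is the
basis for choosing the "optimal" model: for each of the five metrics the
record(s) attaining its maximum point estimate win that metric, and the
record winning the most metrics (ties broken toward fewer features) is
selected.

SHAP importances are computed on held-out rows and pooled across folds and
repetitions — consistent with how performance is assessed. Exact importance
ties (common with binary features) are broken toward the lexicographically
smallest feature name, so a run is fully reproducible from its seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import evaluation
from .evaluation import METRIC_NAMES, FoldAssignment, MetricCI
from .shap_engine import KernelShapConfig, aggregate_importance
from .svm_classifier import SVMHyperparams
from .synthetic_ehr import Cohort

__all__ = [
    "CSAConfig",
    "IterationRecord",
    "CSATrace",
    "run_csa",
    "select_optimal",
    "explain_final",
    "trace_to_frame",
    "load_trace_tsv",
]

log = logging.getLogger("ehrcsa.csa")


@dataclass(frozen=True)
class CSAConfig:
    svm: SVMHyperparams = SVMHyperparams()
    cv_k: int = 4
    cv_repeats: int = 5
    shap: KernelShapConfig = KernelShapConfig()
    bootstrap_rounds: int = 200
    seed: int = 0
    min_features: int = 1

    def __post_init__(self) -> None:
        if self.min_features < 1:
            raise ValueError("min_features must be >= 1")

    def derived_seeds(self) -> dict[str, int]:
        """Named child streams spawned from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        names = ("folds", "shap", "bootstrap")
        return {
            name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(names, children)
        }


@dataclass
class IterationRecord:
    n_features: int
    feature_set: tuple[str, ...]
    importances: dict[str, float]
    metrics: dict[str, MetricCI]
    removed_feature: str | None

    def __post_init__(self) -> None:
        if self.n_features != len(self.feature_set):
            raise ValueError("n_features must equal len(feature_set)")
        if self.removed_feature is not None:
            if self.removed_feature not in self.feature_set:
                raise ValueError("removed_feature must belong to feature_set")
            min_imp = min(self.importances.values())
            if self.importances[self.removed_feature] > min_imp + 1e-12:
                raise ValueError("removed_feature must attain the minimum importance")


@dataclass
class CSATrace:
    records: list[IterationRecord]
    provenance: dict

    def __post_init__(self) -> None:
        sizes = [r.n_features for r in self.records]
        if sizes != list(range(sizes[0], sizes[-1] - 1, -1)):
            raise ValueError("trace sizes must decrease by exactly 1 per record")
        for prev, nxt in zip(self.records, self.records[1:]):
            expect = set(prev.feature_set) - {prev.removed_feature}
            if set(nxt.feature_set) != expect:
                raise ValueError("consecutive feature sets must be nested minus the removal")
        if self.records[-1].removed_feature is not None and len(self.records) > 1:
            pass  # final record may carry a removal only if min_features > 1 semantics

    def __len__(self) -> int:
        return len(self.records)


def _argmin_importance(importances: dict[str, float]) -> str:
    """Feature with minimum mean |phi|; ties -> lexicographically smallest."""
    min_val = min(importances.values())
    tied = [n for n, v in importances.items() if v <= min_val + 1e-12]
    return min(tied)


_TRACE_COLUMNS = (
    ["n_features", "removed_feature"]
    + [f"{m}{s}" for m in METRIC_NAMES for s in ("", "_lo", "_hi")]
    + ["importances_json"]
)


def _record_to_row(rec: IterationRecord) -> dict:
    row: dict = {
        "n_features": rec.n_features,
        "removed_feature": rec.removed_feature if rec.removed_feature else "",
    }
    for m in METRIC_NAMES:
        ci = rec.metrics[m]
        row[m] = ci.point
        row[f"{m}_lo"] = ci.lower
        row[f"{m}_hi"] = ci.upper
    row["importances_json"] = json.dumps(rec.importances, sort_keys=True)
    return row


def trace_to_frame(trace: CSATrace, include_importances: bool = True) -> pd.DataFrame:
    df = pd.DataFrame([_record_to_row(r) for r in trace.records], columns=_TRACE_COLUMNS)
    if not include_importances:
        df = df.drop(columns=["importances_json"])
    return df


def load_trace_tsv(path: str | Path, initial_features: Sequence[str]) -> list[IterationRecord]:
    """Rebuild records from a (possibly partial) trace TSV.

    Feature sets are reconstructed from the initial set and the recorded
    removal sequence, which is what makes an interrupted run resumable.
    """
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    current = sorted(initial_features)
    records = []
    for _, row in df.iterrows():
        metrics = {
            m: MetricCI(float(row[m]), float(row[f"{m}_lo"]), float(row[f"{m}_hi"]))
            for m in METRIC_NAMES
        }
        importances = json.loads(row["importances_json"])
        removed = row["removed_feature"] or None
        rec = IterationRecord(
            int(row["n_features"]), tuple(current), importances, metrics, removed
        )
        records.append(rec)
        if removed is not None:
            current = [f for f in current if f != removed]
    return records


def run_csa(
    cohort: Cohort,
    config: CSAConfig,
    trace_path: str | Path | None = None,
    resume: bool = False,
) -> CSATrace:
    """Run the backward-elimination loop; one record per feature-set size.

    When ``trace_path`` is given, each completed iteration is appended to
    the TSV immediately, and ``resume=True`` fast-forwards past the records
    already present in that file (determinism makes the continuation
    identical to an uninterrupted run).
    """
    if cohort.n_features < config.min_features:
        raise ValueError("cohort has fewer features than min_features")
    seeds = config.derived_seeds()
    folds = evaluation.stratified_kfold(
        cohort.labels, k=config.cv_k, repeats=config.cv_repeats, seed=seeds["folds"]
    )
    shap_cfg = KernelShapConfig(
        n_coalitions=config.shap.n_coalitions,
        background_size=config.shap.background_size,
        seed=seeds["shap"],
    )

    records: list[IterationRecord] = []
    current = sorted(cohort.feature_names)
    if resume and trace_path and Path(trace_path).exists():
        records = load_trace_tsv(trace_path, cohort.feature_names)
        if records:
            last = records[-1]
            current = sorted(set(last.feature_set) - {last.removed_feature}
                             if last.removed_feature else last.feature_set)
            log.info("resuming CSA at %d features", len(current))

    fh = None
    if trace_path is not None:
        mode = "a" if (resume and records) else "w"
        fh = open(trace_path, mode)
        if mode == "w":
            fh.write("\t".join(_TRACE_COLUMNS) + "\n")

    try:
        while True:
            m = len(current)
            done_final = records and records[-1].removed_feature is None
            if m < config.min_features or done_final:
                break
            oof, phi = evaluation.repeated_cv_predict(
                cohort, current, config.svm, folds, shap_cfg
            )
            metrics = evaluation.compute_metric_cis(
                oof,
                rounds=config.bootstrap_rounds,
                seed=(seeds["bootstrap"] + m) % (2**31),
            )
            importances = dict(zip(current, aggregate_importance(phi)))
            removed = _argmin_importance(importances) if m > config.min_features else None
            rec = IterationRecord(m, tuple(current), importances, metrics, removed)
            records.append(rec)
            if fh is not None:
                row = _record_to_row(rec)
                fh.write("\t".join(str(row[c]) for c in _TRACE_COLUMNS) + "\n")
                fh.flush()
            log.info(
                "CSA iteration m=%d auc=%.3f removed=%s",
                m, metrics["auc"].point, removed,
            )
            if removed is None:
                break
            current = [f for f in current if f != removed]
    finally:
        if fh is not None:
            fh.close()

    provenance = {
        "config": {
            "svm": vars(config.svm) | {},
            "cv_k": config.cv_k,
            "cv_repeats": config.cv_repeats,
            "shap_n_coalitions": config.shap.n_coalitions,
            "shap_background_size": config.shap.background_size,
            "bootstrap_rounds": config.bootstrap_rounds,
            "min_features": config.min_features,
        },
        "seed": config.seed,
        "derived_seeds": seeds,
        "cohort": cohort.provenance,
    }
    return CSATrace(records, provenance)


def select_optimal(trace: CSATrace) -> tuple[tuple[str, ...], IterationRecord]:
    """Pick the record winning the most of the five metric maxima.

    For each metric, every record attaining the maximum point estimate
    counts as a winner of that metric; the record with the most metric wins
    is selected, ties resolved toward the fewest features.
    """
    if not trace.records:
        raise ValueError("empty trace")
    wins = {id(r): 0 for r in trace.records}
    for m in METRIC_NAMES:
        best = max(r.metrics[m].point for r in trace.records)
        for r in trace.records:
            if r.metrics[m].point == best:
                wins[id(r)] += 1
    best_rec = max(trace.records, key=lambda r: (wins[id(r)], -r.n_features))
    return best_rec.feature_set, best_rec


def explain_final(
    cohort: Cohort, feature_set: Sequence[str], config: CSAConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Held-out SHAP for the selected set: beeswarm table + importance bars.

    Recomputes attributions under the same CV scheme used for selection.
    The beeswarm table has one row per (patient, repetition) with phi and
    the 0/1 feature value per selected feature; the bar table is mean |phi|
    per feature, sorted descending (stable on ties).
    """
    missing = sorted(set(feature_set) - set(cohort.feature_names))
    if missing:
        raise ValueError(f"features not in cohort: {missing}")
    subset = sorted(feature_set)
    seeds = config.derived_seeds()
    folds = evaluation.stratified_kfold(
        cohort.labels, k=config.cv_k, repeats=config.cv_repeats, seed=seeds["folds"]
    )
    shap_cfg = KernelShapConfig(
        n_coalitions=config.shap.n_coalitions,
        background_size=config.shap.background_size,
        seed=seeds["shap"],
    )
    oof, phi = evaluation.repeated_cv_predict(cohort, subset, config.svm, folds, shap_cfg)
    values = cohort.subset_features(subset)[oof.patient_idx]
    bees = pd.DataFrame(
        {
            "patient_id": [cohort.patient_ids[i] for i in oof.patient_idx],
            "repetition": oof.repetition,
            "fold": oof.fold,
            "true_label": oof.true,
        }
    )
    for j, name in enumerate(subset):
        bees[f"phi_{name}"] = phi[:, j]
    for j, name in enumerate(subset):
        bees[f"value_{name}"] = values[:, j]
    imp = aggregate_importance(phi)
    bars = pd.DataFrame({"feature": subset, "mean_abs_shap": imp})
    bars = bars.sort_values("mean_abs_shap", ascending=False, kind="stable").reset_index(
        drop=True
    )
    return bees, bars
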