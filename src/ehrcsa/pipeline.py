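"""End-to-end experiment orchestration: simulate/ingest -> stats -> CSA -> explain.

``run_experiment`` writes seven artifacts into the output directory:

    cohort.tsv       patient x feature 0/1 matrix
    labels.tsv       patient_id, label
    table1.tsv       case-vs-control summary statistics
    trace.tsv        one row per elimination iteration (metrics + CIs)
    selected.json    the winning feature set and its metrics
    beeswarm.tsv     held-out per-prediction SHAP for the selected set
    importances.tsv  mean |phi| bars for the selected set
    provenance.json  config echo, config hash, seeds, library versions

Every file carries the config hash (TSVs as a leading comment line, JSONs
as a field), so artifacts from different runs cannot be mixed up silently.
A failure part-way leaves previously existing outputs untouched and writes
``error_manifest.json`` instead: artifacts are staged in a temporary
sibling directory and moved into place only after the whole run succeeds.
The master seed spawns named child streams (cohort, folds, shap,
bootstrap), so modules are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
import tempfile
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, cohort_stats, csa as csa_mod, synthetic_ehr
from .config import RunConfig
from .synthetic_ehr import Cohort

__all__ = ["run_experiment", "ARTIFACTS"]

log = logging.getLogger("ehrcsa.pipeline")

ARTIFACTS = (
    "cohort.tsv",
    "labels.tsv",
    "table1.tsv",
    "trace.tsv",
    "selected.json",
    "beeswarm.tsv",
    "importances.tsv",
    "provenance.json",
)


def _cohort_seed(master: int) -> int:
    # one extra named stream alongside CSAConfig's folds/shap/bootstrap
    return int(np.random.SeedSequence((master, 9001)).generate_state(1)[0] % (2**31))


def build_cohort(config: RunConfig) -> Cohort:
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=_cohort_seed(config.seed))
        return synthetic_ehr.generate_cohort(sim)
    labels = synthetic_ehr.read_labels_tsv(config.ingest_labels)
    if config.ingest_matrix is not None:
        return synthetic_ehr.cohort_from_tsv(config.ingest_matrix, config.ingest_labels)
    records = synthetic_ehr.read_records_tsv(config.ingest_records)
    cmap = (
        synthetic_ehr.read_consolidation_tsv(config.ingest_map)
        if config.ingest_map
        else None
    )
    return synthetic_ehr.binarize_problem_lists(records, labels, cmap)


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def run_experiment(config: RunConfig, out_dir: str | Path) -> Path:
    """Run the full pipeline; returns the output directory path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h = config.config_hash
    stage = Path(tempfile.mkdtemp(prefix=".ehrcsa_stage_", dir=out_dir))
    try:
        cohort = build_cohort(config)
        log.info("cohort: %d patients x %d features", cohort.n_patients, cohort.n_features)
        synthetic_ehr.write_matrix_tsv(cohort, stage / "cohort.tsv", f"config_hash={h}")
        with open(stage / "labels.tsv", "w") as fh:
            fh.write(f"# config_hash={h}\n")
            pd.DataFrame(
                {"patient_id": cohort.patient_ids, "label": cohort.labels}
            ).to_csv(fh, sep="\t", index=False)

        binary_vars = (
            list(config.table1_binary)
            if config.table1_binary is not None
            else list(cohort.feature_names)
        )
        table1 = cohort_stats.table1_report(
            cohort, continuous_vars=config.table1_continuous, binary_vars=binary_vars
        )
        _write_tsv(table1, stage / "table1.tsv", h)

        trace = csa_mod.run_csa(cohort, config.csa, trace_path=stage / "trace_raw.tsv")
        df = csa_mod.trace_to_frame(trace, include_importances=False)
        _write_tsv(df, stage / "trace.tsv", h)
        (stage / "trace_raw.tsv").unlink()  # full-fidelity copy only needed mid-run

        feature_set, record = csa_mod.select_optimal(trace)
        wins = {
            m: record.metrics[m].point
            == max(r.metrics[m].point for r in trace.records)
            for m in csa_mod.METRIC_NAMES
        }
        selected = {
            "config_hash": h,
            "features": list(feature_set),
            "n_features": record.n_features,
            "winning_metrics": [m for m, w in wins.items() if w],
            "metrics": {
                m: {
                    "point": record.metrics[m].point,
                    "lower": record.metrics[m].lower,
                    "upper": record.metrics[m].upper,
                }
                for m in csa_mod.METRIC_NAMES
            },
            "provenance": trace.provenance,
        }
        (stage / "selected.json").write_text(json.dumps(selected, indent=2) + "\n")

        bees, bars = csa_mod.explain_final(cohort, feature_set, config.csa)
        _write_tsv(bees, stage / "beeswarm.tsv", h)
        _write_tsv(bars, stage / "importances.tsv", h)

        import sklearn

        provenance = {
            "config_hash": h,
            "config": dict(sorted(config.raw_items.items())),
            "master_seed": config.seed,
            "derived_seeds": {"cohort": _cohort_seed(config.seed)}
            | config.csa.derived_seeds(),
            "versions": {
                "ehrcsa": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scikit-learn": sklearn.__version__,
            },
        }
        (stage / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")

        for name in ARTIFACTS:
            shutil.move(str(stage / name), str(out_dir / name))
        manifest = out_dir / "error_manifest.json"
        if manifest.exists():
            manifest.unlink()
        return out_dir
    except Exception as exc:  # leave prior outputs intact, record the failure
        (out_dir / "error_manifest.json").write_text(
            json.dumps(
                {
                    "config_hash": h,
                    "error": f"{type(exc).__name__}: {exc}",
                    "traceback": traceback.format_exc(),
                },
                indent=2,
            )
            + "\n"
        )
        raise
    finally:
        shutil.rmtree(stage, ignore_errors=True)
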