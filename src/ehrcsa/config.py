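"""Flat key-value run configuration for the end-to-end experiment.

The config file is plain text, one ``key = value`` per line, ``#`` comments
allowed. Unknown keys are hard errors. Exactly one input mode must be
configured: either ``simulate.*`` keys (synthetic cohort) or ``ingest.*``
paths (a pre-binarized matrix, or long-format records).

Recognized keys and defaults::

    seed = 0                     master seed; spawns all module streams
    simulate.n_cases = 23
    simulate.n_controls = 25
    simulate.n_features = 319
    simulate.informative = name:p_case:p_control,...   (optional)
    simulate.titer = on|off      lognormal serum-marker metadata (default off)
    ingest.matrix = <tsv>        pre-binarized patient x feature matrix
    ingest.records = <tsv>       long-format patient_id/item records
    ingest.labels = <tsv>        required with either ingest mode
    ingest.map = <tsv>           optional consolidation map
    svm.C = 1.0
    svm.gamma = scale            positive real or "scale"
    svm.class_weight = none      none | balanced
    cv.k = 4
    cv.repeats = 5
    shap.n_coalitions = auto     int, "auto" (2M+512) or "all"
    shap.background_size = 16
    bootstrap.rounds = 200
    csa.min_features = 1
    table1.continuous =          comma-separated metadata columns (optional)
    table1.binary =              comma-separated feature names; default: all
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

from .csa import CSAConfig
from .shap_engine import KernelShapConfig
from .svm_classifier import SVMHyperparams
from .synthetic_ehr import CohortConfig, InformativeFeature, TiterParams

__all__ = ["ConfigError", "RunConfig", "parse_config_file", "parse_config_text"]

_KNOWN_KEYS = {
    "seed",
    "simulate.n_cases", "simulate.n_controls", "simulate.n_features",
    "simulate.informative", "simulate.titer",
    "ingest.matrix", "ingest.records", "ingest.labels", "ingest.map",
    "svm.C", "svm.gamma", "svm.class_weight",
    "cv.k", "cv.repeats",
    "shap.n_coalitions", "shap.background_size",
    "bootstrap.rounds", "csa.min_features",
    "table1.continuous", "table1.binary",
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated experiment configuration plus its canonical text and hash."""

    seed: int
    simulate: CohortConfig | None
    ingest_matrix: str | None
    ingest_records: str | None
    ingest_labels: str | None
    ingest_map: str | None
    csa: CSAConfig
    table1_continuous: tuple[str, ...]
    table1_binary: tuple[str, ...] | None  # None -> all features
    raw_items: dict[str, str] = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        canonical = "\n".join(f"{k} = {v}" for k, v in sorted(self.raw_items.items()))
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _parse_informative(text: str) -> list[InformativeFeature]:
    out = []
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        bits = part.split(":")
        if len(bits) != 3:
            raise ConfigError(
                f"simulate.informative entries must be name:p_case:p_control, got {part!r}"
            )
        out.append(InformativeFeature(bits[0], float(bits[1]), float(bits[2])))
    return out


def parse_config_text(text: str) -> RunConfig:
    items: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in _KNOWN_KEYS:
            raise ConfigError(f"line {lineno}: unknown key {key!r}")
        if key in items:
            raise ConfigError(f"line {lineno}: duplicate key {key!r}")
        items[key] = value

    def get(key: str, default: str) -> str:
        return items.get(key, default)

    seed = int(get("seed", "0"))
    has_sim = any(k.startswith("simulate.") for k in items)
    has_ing = any(k.startswith("ingest.") for k in items)
    if has_sim and has_ing:
        raise ConfigError("config mixes simulate.* and ingest.* keys; pick one mode")
    if not has_sim and not has_ing:
        has_sim = True  # default: simulate with all defaults

    simulate = None
    ingest_matrix = ingest_records = ingest_labels = ingest_map = None
    if has_sim:
        informative = _parse_informative(get("simulate.informative", ""))
        titer = get("simulate.titer", "off")
        if titer not in ("on", "off"):
            raise ConfigError("simulate.titer must be on or off")
        # cohort seed is derived from the master seed at run time
        simulate = CohortConfig(
            n_cases=int(get("simulate.n_cases", "23")),
            n_controls=int(get("simulate.n_controls", "25")),
            n_features=int(get("simulate.n_features", "319")),
            informative_features=tuple(informative),
            titer=TiterParams() if titer == "on" else None,
        )
        simulate.validate()
    else:
        ingest_matrix = items.get("ingest.matrix")
        ingest_records = items.get("ingest.records")
        ingest_labels = items.get("ingest.labels")
        ingest_map = items.get("ingest.map")
        if ingest_labels is None:
            raise ConfigError("ingest mode requires ingest.labels")
        if (ingest_matrix is None) == (ingest_records is None):
            raise ConfigError("ingest mode requires exactly one of ingest.matrix / ingest.records")

    gamma_raw = get("svm.gamma", "scale")
    gamma: float | str = gamma_raw if gamma_raw == "scale" else float(gamma_raw)
    n_coal_raw = get("shap.n_coalitions", "auto")
    n_coal: int | str = n_coal_raw if n_coal_raw in ("auto", "all") else int(n_coal_raw)
    csa_cfg = CSAConfig(
        svm=SVMHyperparams(
            C=float(get("svm.C", "1.0")),
            gamma=gamma,
            class_weight=get("svm.class_weight", "none"),
        ),
        cv_k=int(get("cv.k", "4")),
        cv_repeats=int(get("cv.repeats", "5")),
        shap=KernelShapConfig(
            n_coalitions=n_coal,
            background_size=int(get("shap.background_size", "16")),
        ),
        bootstrap_rounds=int(get("bootstrap.rounds", "200")),
        seed=seed,
        min_features=int(get("csa.min_features", "1")),
    )

    cont = tuple(s.strip() for s in get("table1.continuous", "").split(",") if s.strip())
    binary_raw = get("table1.binary", "")
    binary = (
        tuple(s.strip() for s in binary_raw.split(",") if s.strip()) if binary_raw else None
    )
    return RunConfig(
        seed=seed,
        simulate=simulate,
        ingest_matrix=ingest_matrix,
        ingest_records=ingest_records,
        ingest_labels=ingest_labels,
        ingest_map=ingest_map,
        csa=csa_cfg,
        table1_continuous=cont,
        table1_binary=binary,
        raw_items=items,
    )


def parse_config_file(path: str | Path) -> RunConfig:
    return parse_config_text(Path(path).read_text())
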