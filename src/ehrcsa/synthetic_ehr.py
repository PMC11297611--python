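"""Synthetic case-control cohorts of binary problem-list features, and ingest.

Real problem-list data are sparse 0/1 indicators ("hypothyroidism present
in this patient's past medical history"). This module generates cohorts
with *known planted structure* — a handful of features whose prevalence
differs between cases and controls, embedded in background features whose
prevalence is shared by both classes — so that every downstream stage
(classifier, attribution, selection loop) can be tested against ground
truth. It also ingests real-format long records (patient_id, item) and
binarizes them into the same in-memory container.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfigError",
    "IngestError",
    "InformativeFeature",
    "TiterParams",
    "CohortConfig",
    "Cohort",
    "ProblemListRecord",
    "generate_cohort",
    "binarize_problem_lists",
    "cohort_to_records",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_labels_tsv",
    "write_labels_tsv",
    "read_records_tsv",
    "read_consolidation_tsv",
]


class CohortConfigError(ValueError):
    """Invalid cohort generator configuration; the message names the field."""


class IngestError(ValueError):
    """Problem-list records inconsistent with the label file."""


@dataclass(frozen=True)
class InformativeFeature:
    """A planted feature with class-specific prevalence."""

    name: str
    prevalence_cases: float
    prevalence_controls: float


@dataclass(frozen=True)
class TiterParams:
    """Lognormal parameters for a cosmetic per-patient serum marker level.

    ``meanlog``/``sdlog`` are the parameters of log(titer) per class, in the
    units of the marker (nmol/L). Purely metadata: never enters the feature
    matrix.
    """

    meanlog_cases: float = 3.87
    sdlog_cases: float = 1.56
    meanlog_controls: float = 3.36
    sdlog_controls: float = 1.55


@dataclass
class CohortConfig:
    """Configuration of the synthetic cohort generator.

    Defaults mirror the study conditions this package emulates: 23 cases and
    25 controls with 319 binary past-medical-history items. Background
    (non-planted) features draw a single prevalence per feature, shared by
    both classes, from Beta(0.6, 5) — median around 0.08, reflecting the
    sparsity of problem lists.
    """

    n_cases: int = 23
    n_controls: int = 25
    n_features: int = 319
    informative_features: Sequence[InformativeFeature] = ()
    noise_prevalence_alpha: float = 0.6
    noise_prevalence_beta: float = 5.0
    noise_prevalence_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None
    seed: int = 0
    titer: TiterParams | None = None
    # Optional block correlation: features within a block copy a shared
    # latent Bernoulli draw with probability ``block_rho`` (off by default;
    # real problem lists co-occur, independent columns do not).
    block_size: int = 1
    block_rho: float = 0.0

    def validate(self) -> None:
        if self.n_cases <= 0:
            raise CohortConfigError("n_cases must be > 0")
        if self.n_controls <= 0:
            raise CohortConfigError("n_controls must be > 0")
        if self.n_features < len(self.informative_features):
            raise CohortConfigError(
                "n_features must be >= number of informative_features"
            )
        if self.n_features <= 0:
            raise CohortConfigError("n_features must be > 0")
        names = [f.name for f in self.informative_features]
        if len(set(names)) != len(names):
            raise CohortConfigError("informative_features names must be unique")
        for f in self.informative_features:
            for attr in ("prevalence_cases", "prevalence_controls"):
                p = getattr(f, attr)
                if not (0.0 <= p <= 1.0):
                    raise CohortConfigError(
                        f"informative_features[{f.name!r}].{attr} must be in [0,1], got {p}"
                    )
        if self.noise_prevalence_alpha <= 0 or self.noise_prevalence_beta <= 0:
            raise CohortConfigError("noise prevalence Beta parameters must be > 0")
        if self.block_size < 1:
            raise CohortConfigError("block_size must be >= 1")
        if not (0.0 <= self.block_rho <= 1.0):
            raise CohortConfigError("block_rho must be in [0,1]")


@dataclass(frozen=True)
class ProblemListRecord:
    """One verbatim problem-list entry for one patient."""

    patient_id: str
    item: str

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise IngestError("patient_id must be non-empty")
        if not self.item:
            raise IngestError("item must be non-empty")


@dataclass
class Cohort:
    """Patient x feature binary matrix with labels — the universal input.

    ``matrix`` holds strictly 0/1 entries; ``labels`` is 1 for cases.
    ``metadata`` optionally carries patient-level continuous covariates
    (e.g. a serum titer) for the summary statistics, indexed like
    ``patient_ids``.
    """

    matrix: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    patient_ids: list[str]
    provenance: str = ""
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        self.labels = np.asarray(self.labels)
        n, p = self.matrix.shape
        if len(self.labels) != n:
            raise ValueError("labels length must equal matrix row count")
        if len(self.feature_names) != p:
            raise ValueError("feature_names length must equal matrix column count")
        if len(self.patient_ids) != n:
            raise ValueError("patient_ids length must equal matrix row count")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature_names must be unique")
        if len(set(self.patient_ids)) != n:
            raise ValueError("patient_ids must be unique")
        if self.matrix.size and not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("matrix entries must be binary 0/1")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if self.labels.sum() == 0 or self.labels.sum() == n:
            raise ValueError("cohort must contain at least one case and one control")

    @property
    def n_patients(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def subset_features(self, names: Sequence[str]) -> np.ndarray:
        """Column-restricted view of the matrix, in the order given."""
        idx = [self.feature_names.index(n) for n in names]
        return self.matrix[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=pd.Index(self.patient_ids, name="patient_id"),
            columns=self.feature_names,
        )


def _noise_feature_names(n: int, taken: set[str]) -> list[str]:
    width = max(4, len(str(n)))
    out = []
    i = 1
    while len(out) < n:
        name = f"phx_item_{i:0{width}d}"
        if name not in taken:
            out.append(name)
        i += 1
    return out


def generate_cohort(config: CohortConfig) -> Cohort:
    """Sample a case-control cohort of Bernoulli problem-list features.

    Informative columns use class-specific prevalences; every other column
    uses a single background prevalence drawn once from the noise sampler
    and shared by both classes. Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_cases, n_controls = config.n_cases, config.n_controls
    n = n_cases + n_controls
    p = config.n_features

    info = list(config.informative_features)
    n_noise = p - len(info)
    taken = {f.name for f in info}
    names = [f.name for f in info] + _noise_feature_names(n_noise, taken)

    # Per-column prevalence per class (cases row 0, controls row 1).
    prev = np.empty((2, p))
    for j, f in enumerate(info):
        prev[0, j] = f.prevalence_cases
        prev[1, j] = f.prevalence_controls
    if n_noise:
        if config.noise_prevalence_sampler is not None:
            noise_p = np.asarray(config.noise_prevalence_sampler(rng, n_noise), float)
            if noise_p.shape != (n_noise,) or (noise_p < 0).any() or (noise_p > 1).any():
                raise CohortConfigError(
                    "noise_prevalence_sampler must return n values in [0,1]"
                )
        else:
            noise_p = rng.beta(
                config.noise_prevalence_alpha, config.noise_prevalence_beta, n_noise
            )
        prev[:, len(info):] = noise_p

    labels = np.concatenate([np.ones(n_cases, int), np.zeros(n_controls, int)])
    row_prev = prev[1 - labels]  # (n, p): each patient's per-feature prevalence
    matrix = (rng.random((n, p)) < row_prev).astype(np.int8)

    if config.block_size > 1 and config.block_rho > 0.0:
        # Features in a block copy a shared latent draw (at the block's mean
        # prevalence) with probability rho, inducing within-block correlation.
        for start in range(0, p, config.block_size):
            cols = slice(start, min(start + config.block_size, p))
            width = cols.stop - cols.start
            if width < 2:
                continue
            block_prev = row_prev[:, cols].mean(axis=1)
            latent = (rng.random(n) < block_prev).astype(np.int8)
            share = rng.random((n, width)) < config.block_rho
            sub = matrix[:, cols]
            sub[share] = np.broadcast_to(latent[:, None], (n, width))[share]
            matrix[:, cols] = sub

    # Lexicographic column order for deterministic downstream tie-breaking.
    order = np.argsort(names, kind="stable")
    matrix = matrix[:, order]
    names = [names[i] for i in order]

    ids = [f"case_{i+1:03d}" for i in range(n_cases)] + [
        f"ctrl_{i+1:03d}" for i in range(n_controls)
    ]

    metadata = None
    if config.titer is not None:
        t = config.titer
        titer = np.where(
            labels == 1,
            rng.lognormal(t.meanlog_cases, t.sdlog_cases, n),
            rng.lognormal(t.meanlog_controls, t.sdlog_controls, n),
        )
        metadata = pd.DataFrame(
            {"anti_gad65_titer": titer}, index=pd.Index(ids, name="patient_id")
        )

    prov = (
        f"generate_cohort(seed={config.seed}, n_cases={n_cases}, "
        f"n_controls={n_controls}, n_features={p}, "
        f"informative={[f.name for f in info]})"
    )
    return Cohort(matrix, labels, names, ids, provenance=prov, metadata=metadata)


def _canonical(item: str) -> str:
    return item.strip().casefold()


def binarize_problem_lists(
    records: Sequence[ProblemListRecord],
    labels: Mapping[str, int],
    consolidation_map: Mapping[str, str] | None = None,
) -> Cohort:
    """Binarize long-format problem-list records into a 0/1 cohort matrix.

    The vocabulary is the sorted set of canonical item names after applying
    the consolidation map (items are case-folded and whitespace-stripped
    before lookup; unmapped items keep their canonical string). Entry
    (patient, feature) is 1 iff the patient has at least one record mapping
    to the feature — merging synonyms is a logical OR. Patients that appear
    in ``labels`` but have no records become all-zero rows.
    """
    cmap = {}
    if consolidation_map:
        for k, v in consolidation_map.items():
            target = v.strip()
            cmap[_canonical(k)] = target
    unknown = sorted({r.patient_id for r in records} - set(labels))
    if unknown:
        raise IngestError(
            f"records reference patient ids absent from labels: {unknown}"
        )

    mapped: list[tuple[str, str]] = []
    for r in records:
        canon = _canonical(r.item)
        canon = cmap.get(canon, canon)
        if canon:
            mapped.append((r.patient_id, canon))
    if records and not mapped:
        raise IngestError("consolidation map produced an empty vocabulary")
    if not records:
        warnings.warn("no problem-list records: cohort has zero feature columns")

    vocab = sorted({item for _, item in mapped})
    patients = sorted(labels)
    col = {f: j for j, f in enumerate(vocab)}
    row = {pid: i for i, pid in enumerate(patients)}
    matrix = np.zeros((len(patients), len(vocab)), np.int8)
    for pid, item in mapped:
        matrix[row[pid], col[item]] = 1
    y = np.array([labels[pid] for pid in patients], int)
    return Cohort(
        matrix, y, vocab, patients,
        provenance=f"binarize_problem_lists({len(records)} records, "
        f"{len(patients)} patients, map_size={len(cmap)})",
    )


def cohort_to_records(cohort: Cohort) -> list[ProblemListRecord]:
    """Export a cohort back to long-format records (round-trip support)."""
    out = []
    for i, pid in enumerate(cohort.patient_ids):
        for j in np.flatnonzero(cohort.matrix[i]):
            out.append(ProblemListRecord(pid, cohort.feature_names[j]))
    return out


# --- Plain-text interchange: TSV readers/writers -------------------------

def write_matrix_tsv(cohort: Cohort, path: str | Path, header_comment: str = "") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        cohort.to_frame().to_csv(fh, sep="\t")


def read_matrix_tsv(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Read a matrix TSV -> (frame indexed by patient_id, feature names)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col="patient_id", dtype=str)
    df = df.astype(int)
    bad = df.values[~np.isin(df.values, (0, 1))]
    if bad.size:
        raise IngestError(f"matrix entries must be 0/1; saw {sorted(set(bad))[:5]}")
    return df, list(df.columns)


def write_labels_tsv(cohort: Cohort, path: str | Path) -> None:
    pd.DataFrame(
        {"patient_id": cohort.patient_ids, "label": cohort.labels}
    ).to_csv(path, sep="\t", index=False)


def read_labels_tsv(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"patient_id": str})
    if not {"patient_id", "label"} <= set(df.columns):
        raise IngestError("labels TSV must have columns patient_id, label")
    labels = dict(zip(df["patient_id"], df["label"].astype(int)))
    bad = sorted({v for v in labels.values() if v not in (0, 1)})
    if bad:
        raise IngestError(f"labels must be 0/1; saw {bad}")
    return labels


def read_records_tsv(path: str | Path) -> list[ProblemListRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"patient_id", "item"} <= set(df.columns):
        raise IngestError("records TSV must have columns patient_id, item")
    return [ProblemListRecord(p, i) for p, i in zip(df["patient_id"], df["item"])]


def read_consolidation_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"item", "canonical"} <= set(df.columns):
        raise IngestError("consolidation TSV must have columns item, canonical")
    return dict(zip(df["item"], df["canonical"]))


def cohort_from_tsv(
    matrix_path: str | Path, labels_path: str | Path
) -> Cohort:
    """Load a pre-binarized cohort from matrix + labels TSVs."""
    frame, names = read_matrix_tsv(matrix_path)
    labels = read_labels_tsv(labels_path)
    missing = sorted(set(frame.index) - set(labels))
    if missing:
        raise IngestError(f"matrix patients missing from labels: {missing}")
    y = np.array([labels[p] for p in frame.index], int)
    return Cohort(
        frame.values.astype(np.int8), y, names, list(frame.index),
        provenance=f"cohort_from_tsv({matrix_path})",
    )
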