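"""Cohort preprocessing: binarization, endpoint selection and resampling.

A continuous expression cohort (log fold-changes with missing values, plus
per-patient survival time and event status) is reduced to the binary
classification matrix the tree classifiers consume: expression entries
become 1 when the log ratio is strictly positive and 0 otherwise (negative,
zero or missing), and the outcome label is the patient's survival status at
a fixed endpoint ``t_end`` — 1 if they died of disease before ``t_end``,
0 if followed up alive past it, and excluded entirely when censoring leaves
the status at ``t_end`` unknown.  Choosing ``t_end`` to balance the two
classes is supported, as is a shared train/test resampling plan so every
classifier sees identical splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

EXCLUDED = "EXCLUDED"


class Event(str, Enum):
    """Per-patient outcome status at last follow-up."""

    DEATH_DISEASE = "death_disease"
    DEATH_OTHER = "death_other"
    ALIVE = "alive"


@dataclass
class ExpressionCohort:
    """Continuous expression + survival data for a patient cohort.

    ``log_ratios`` is a patient x gene matrix of real log fold-changes with
    NaN marking missing measurements.  ``survival_time`` is years from
    diagnosis to death or last follow-up; ``event`` says which.
    """

    patient_ids: list[str]
    gene_ids: list[str]
    log_ratios: np.ndarray
    survival_time: np.ndarray
    event: list[Event]

    def __post_init__(self):
        self.log_ratios = np.asarray(self.log_ratios, dtype=float)
        self.survival_time = np.asarray(self.survival_time, dtype=float)
        n, p = self.log_ratios.shape
        if len(self.patient_ids) != n or len(self.gene_ids) != p:
            raise ValueError("matrix dimensions must match id list lengths")
        if len(self.survival_time) != n or len(self.event) != n:
            raise ValueError("survival data length mismatch")
        if np.isnan(self.survival_time).any():
            raise ValueError("survival_time may not be missing")
        if (self.survival_time < 0).any():
            raise ValueError("survival_time must be >= 0")
        self.event = [Event(e) for e in self.event]

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)


@dataclass
class BinaryDataset:
    """The binary matrix H: {0,1} features plus the {0,1} outcome column.

    Label 1 means dead of disease before the endpoint; the layout mirrors
    the classic 71-column table with the target as the final column.
    """

    features: np.ndarray
    labels: np.ndarray
    patient_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.int8)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        n, p = self.features.shape
        if len(self.labels) != n:
            raise ValueError("label vector length must equal number of rows")
        if not np.isin(self.features, (0, 1)).all() or not np.isin(
            self.labels, (0, 1)
        ).all():
            raise ValueError("all entries must be 0/1")
        if not self.patient_ids:
            self.patient_ids = [f"P{i}" for i in range(n)]
        if not self.gene_ids:
            self.gene_ids = [f"G{j}" for j in range(p)]
        if len(self.patient_ids) != n or len(self.gene_ids) != p:
            raise ValueError("id list lengths must match matrix dimensions")

    @property
    def n_patients(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, index=self.patient_ids, columns=self.gene_ids)
        df["label"] = self.labels
        return df

    def subset(self, rows) -> "BinaryDataset":
        rows = np.asarray(rows)
        return BinaryDataset(
            self.features[rows],
            self.labels[rows],
            [self.patient_ids[i] for i in rows],
            list(self.gene_ids),
        )


@dataclass(frozen=True)
class SplitPlan:
    """Shared train/test partitions reused identically by every method."""

    runs: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]
    master_seed: int

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def binarize_expression(cohort: ExpressionCohort | np.ndarray) -> np.ndarray:
    """Binarize log fold-changes: strictly positive -> 1; negative, zero or missing -> 0."""
    M = cohort.log_ratios if isinstance(cohort, ExpressionCohort) else np.asarray(cohort)
    if not np.issubdtype(M.dtype, np.number):
        raise ValueError("expression matrix contains non-numeric entries")
    with np.errstate(invalid="ignore"):
        return (M > 0).astype(np.int8)


def derive_outcome(
    survival_time: float,
    event: Event | str,
    t_end: float,
    death_other_as_censored: bool = False,
) -> int | str:
    """Survival status at ``t_end``: 1 dead of disease before it, 0 alive past it.

    Censoring before ``t_end`` (alive with short follow-up) leaves the
    status unknown and returns :data:`EXCLUDED`.  Death from other causes is
    excluded by default; with ``death_other_as_censored`` it is treated as
    censoring at the time of death instead.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if survival_time < 0:
        raise ValueError("negative survival time")
    event = Event(event)
    if event is Event.DEATH_DISEASE:
        return 1 if survival_time < t_end else 0
    if event is Event.DEATH_OTHER and not death_other_as_censored:
        return EXCLUDED
    # alive (or other-cause death treated as censoring): status known only
    # if follow-up reaches t_end
    return 0 if survival_time >= t_end else EXCLUDED


def derive_labels(
    cohort: ExpressionCohort, t_end: float, death_other_as_censored: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized outcome derivation: (labels, boolean eligibility mask)."""
    out = [
        derive_outcome(t, e, t_end, death_other_as_censored)
        for t, e in zip(cohort.survival_time, cohort.event)
    ]
    mask = np.array([o != EXCLUDED for o in out])
    labels = np.array([o if o != EXCLUDED else 0 for o in out], dtype=np.int8)
    return labels, mask


def select_balanced_endpoint(
    cohort: ExpressionCohort,
    candidate_grid: list[float] | None = None,
    death_other_as_censored: bool = False,
) -> float:
    """Pick the endpoint that best balances dead vs alive patients.

    Among the candidate cutoffs the one minimizing |#dead - #alive| over the
    eligible (non-excluded) patients wins, ties going to the smallest
    cutoff.  By default the grid is every observed disease-death time, so
    the balancing is data-driven; a single-element grid acts as a fixed
    cutoff (used for deliberately unbalanced analyses).
    """
    if candidate_grid is None:
        candidate_grid = sorted(
            {
                float(t)
                for t, e in zip(cohort.survival_time, cohort.event)
                if e is Event.DEATH_DISEASE and t > 0
            }
        )
    if not candidate_grid:
        raise ValueError("empty candidate grid")
    best_t, best_imbalance = None, None
    for t_end in sorted(candidate_grid):
        labels, mask = derive_labels(cohort, t_end, death_other_as_censored)
        n_eligible = int(mask.sum())
        if n_eligible == 0:
            continue
        n1 = int(labels[mask].sum())
        imbalance = abs(n1 - (n_eligible - n1))
        if best_imbalance is None or imbalance < best_imbalance:
            best_t, best_imbalance = t_end, imbalance
    if best_t is None:
        raise ValueError("no grid point yields eligible patients")
    return float(best_t)


def make_binary_dataset(
    cohort: ExpressionCohort, t_end: float, death_other_as_censored: bool = False
) -> BinaryDataset:
    """Binarize expression and derive outcomes, dropping excluded patients."""
    X = binarize_expression(cohort)
    labels, mask = derive_labels(cohort, t_end, death_other_as_censored)
    keep = np.flatnonzero(mask)
    return BinaryDataset(
        X[keep],
        labels[keep],
        [cohort.patient_ids[i] for i in keep],
        list(cohort.gene_ids),
    )


def make_splits(
    n: int, train_fraction: float, n_runs: int, master_seed: int
) -> SplitPlan:
    """Independent random train/test partitions, reproducible from the seed.

    Test size is ``round(n * (1 - train_fraction))`` — 44 patients when
    n = 148 at a 70/30 split.  Each run draws from its own RNG stream
    seeded by (master_seed, run index), so extending ``n_runs`` never
    changes earlier splits.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if n < 2:
        raise ValueError("need at least 2 patients")
    n_test = int(np.floor(n * (1 - train_fraction) + 0.5))
    if n_test == 0 or n_test == n:
        raise ValueError("train_fraction produces an empty train or test set")
    runs = []
    for r in range(n_runs):
        rng = np.random.default_rng([master_seed, r])
        perm = rng.permutation(n)
        test = np.sort(perm[:n_test])
        train = np.sort(perm[n_test:])
        runs.append((tuple(int(i) for i in train), tuple(int(i) for i in test)))
    return SplitPlan(runs=tuple(runs), master_seed=master_seed)


# ---------------------------------------------------------------------------
# file I/O: TSV expression matrix + clinical table, binary-matrix writer

def read_expression_tsv(
    expression_path: str | Path, clinical_path: str | Path
) -> ExpressionCohort:
    """Read a cohort from TSV files.

    The expression file has one patient per row, a ``patient_id`` column and
    one column per gene; missing values are empty fields or "NA".  The
    clinical table has columns ``patient_id``, ``survival_years`` and
    ``event`` in {death_disease, death_other, alive}.
    """
    expr = pd.read_csv(expression_path, sep="\t", na_values=["NA", ""])
    clin = pd.read_csv(clinical_path, sep="\t")
    expr = expr.set_index("patient_id")
    clin = clin.set_index("patient_id").loc[expr.index]
    return ExpressionCohort(
        patient_ids=[str(i) for i in expr.index],
        gene_ids=[str(c) for c in expr.columns],
        log_ratios=expr.to_numpy(dtype=float),
        survival_time=clin["survival_years"].to_numpy(dtype=float),
        event=[Event(e) for e in clin["event"]],
    )


def write_binary_tsv(dataset: BinaryDataset, path: str | Path) -> None:
    """Write the binary matrix H with the label as the final column."""
    df = dataset.to_frame()
    df.index.name = "patient_id"
    df.to_csv(path, sep="\t")


def read_binary_tsv(path: str | Path) -> BinaryDataset:
    df = pd.read_csv(path, sep="\t", index_col="patient_id")
    return BinaryDataset(
        features=df.drop(columns=["label"]).to_numpy(),
        labels=df["label"].to_numpy(),
        patient_ids=[str(i) for i in df.index],
        gene_ids=[str(c) for c in df.columns if c != "label"],
    )
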