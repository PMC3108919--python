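"""Confusion metrics, run summaries and comparison statistics.

Classical tests only: one-way fixed-effects ANOVA across method groups,
pairwise two-sided equal-variance Student t-tests of GP against each
comparator, and the two-sided Fisher exact test of a tree's predictions
against true outcomes on an external cohort.  No multiple-testing
correction is applied: the raw pairwise p-values are reported, matching
the study design this package reproduces.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .preprocessing import BinaryDataset
    from .trees import BoolTree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/TN/FN counts for one classifier on one test set.

    The positive class is death of disease before the endpoint, so a false
    negative is a patient who died but was predicted to survive.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def errors(self) -> int:
        """Total incorrectly classified instances."""
        return self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    def as_table(self) -> np.ndarray:
        """2x2 contingency table [[tp, fn], [fp, tn]] (prediction vs truth)."""
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


def confusion(predictions, labels) -> ConfusionMatrix:
    """Tally the 2x2 confusion counts of binary predictions against labels."""
    p = np.asarray(predictions)
    y = np.asarray(labels)
    if p.shape != y.shape:
        raise ValueError("predictions and labels must have identical length")
    if not (np.isin(p, (0, 1)).all() and np.isin(y, (0, 1)).all()):
        raise ValueError("entries must be binary")
    return ConfusionMatrix(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


@dataclass(frozen=True)
class MethodSummary:
    """Best / mean / SEM of per-run error counts for one method."""

    method: str
    errors: tuple[float, ...]
    best: float
    mean: float
    sem: float


def summarize_runs(errors: Sequence[float], method: str = "") -> MethodSummary:
    """Best (minimum), mean and standard error of the mean over runs.

    SEM is the sample standard deviation (ddof=1) divided by sqrt(runs),
    so at least two runs are required.
    """
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("no runs to summarize")
    if e.size < 2:
        raise ValueError("SEM requires at least 2 runs")
    return MethodSummary(
        method=method,
        errors=tuple(float(x) for x in e),
        best=float(e.min()),
        mean=float(e.mean()),
        sem=float(e.std(ddof=1) / np.sqrt(e.size)),
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> float:
    """Classical one-way fixed-effects ANOVA p-value across method groups.

    Degenerate input with zero variance everywhere and equal means returns
    p = 1 by convention.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(g.var() == 0 for g in gs) and len({float(g.mean()) for g in gs}) == 1:
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = stats.f_oneway(*gs)
    return 1.0 if np.isnan(p) else float(p)


def two_tailed_t_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided two-sample Student t-test p-value, pooled (equal) variance.

    The equal-variance form is used throughout; when an F-test of the two
    variances rejects at the 0.05 level a warning is logged, since the
    pooled test may then be anti-conservative.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va > 0 and vb > 0:
        f = va / vb
        p_var = 2 * min(
            stats.f.cdf(f, a.size - 1, b.size - 1),
            stats.f.sf(f, a.size - 1, b.size - 1),
        )
        if p_var < 0.05:
            logger.warning(
                "variance F-test rejects equality (p=%.3g); pooled t-test may "
                "be unreliable",
                p_var,
            )
    if va == 0 and vb == 0 and a.mean() == b.mean():
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = stats.ttest_ind(a, b, equal_var=True)
    return 1.0 if np.isnan(p) else float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value on a 2x2 count table.

    A table with an all-zero margin carries no information about
    association and returns p = 1; an all-zero table is an error.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p)


@dataclass(frozen=True)
class ExternalValidationResult:
    """Outcome of applying one frozen tree to an external cohort."""

    tree: "BoolTree"
    applicable: bool
    confusion: ConfusionMatrix | None
    fisher_p: float | None


def external_validation(
    trees: Sequence["BoolTree"],
    external: "BinaryDataset",
    gene_map: dict[int, int | None],
) -> list[ExternalValidationResult]:
    """Apply frozen GP solutions to an independent cohort with no retraining.

    ``gene_map`` maps each signature feature index to the matching column
    of the external dataset, or ``None`` when the platform lacks the gene.
    A tree is applicable only if every terminal it uses maps; applicable
    trees are evaluated as-is and their 2x2 prediction-vs-outcome table is
    Fisher-tested.  Inapplicable trees are reported, never raised.
    """
    X = np.asarray(external.features)
    y = np.asarray(external.labels)
    out = []
    for tree in trees:
        mapping = {t: gene_map.get(t) for t in tree.terminals}
        if any(v is None for v in mapping.values()):
            out.append(ExternalValidationResult(tree, False, None, None))
            continue
        remapped = tree.remap({k: int(v) for k, v in mapping.items()})
        cm = confusion(remapped.evaluate(X), y)
        out.append(
            ExternalValidationResult(tree, True, cm, fisher_exact_2x2(cm.as_table()))
        )
    return out
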