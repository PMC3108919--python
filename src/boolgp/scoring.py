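"""The correlation-scoring baseline of the original 70-gene signature.

Each patient's prognosis score *s* is the Pearson correlation between
their 70-gene expression profile and a previously derived "good prognosis"
centroid profile; patients with s > 0.4 are called good prognosis and
s <= 0.4 bad prognosis (the boundary itself is bad).  The centroid is an
input — its derivation belongs to the signature's original training cohort
and is never recomputed here — and precomputed scores may be supplied
directly instead of profiles.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import MethodSummary, summarize_runs

GOOD, BAD = "good", "bad"

DEFAULT_CUTOFF = 0.4


def correlation_score(profile, centroid) -> float:
    """Pearson correlation of a patient profile with the good-prognosis centroid."""
    p = np.asarray(profile, dtype=float)
    c = np.asarray(centroid, dtype=float)
    if p.shape != c.shape or p.ndim != 1:
        raise ValueError("profile and centroid must be 1-D of equal length")
    if p.std() == 0 or c.std() == 0:
        raise ValueError("zero-variance vector: correlation score undefined")
    return float(stats.pearsonr(p, c).statistic)


def classify_by_score(s: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """Good prognosis iff s strictly exceeds the cutoff; s == cutoff is bad."""
    return GOOD if s > cutoff else BAD


def score_errors(scores, labels, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Per-patient 0/1 indicator of a false prediction.

    A good-prognosis call on a patient who died (label 1) is this
    baseline's false negative; a bad-prognosis call on a survivor (label 0)
    its false positive.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels length mismatch")
    good = s > cutoff
    return ((good & (y == 1)) | (~good & (y == 0))).astype(np.int8)


def evaluate_scoring(
    scores,
    labels,
    sample_lists: Sequence[Sequence[int]],
    cutoff: float = DEFAULT_CUTOFF,
) -> MethodSummary:
    """False-prediction count per resampled patient list, with mean and SEM."""
    wrong = score_errors(scores, labels, cutoff)
    counts = []
    for lst in sample_lists:
        idx = np.asarray(lst)
        if idx.size == 0:
            raise ValueError("empty sample list")
        counts.append(int(wrong[idx].sum()))
    return summarize_runs(counts, method="scoring")


def scoring_false_negatives(
    scores, labels, sample_lists: Sequence[Sequence[int]], cutoff: float = DEFAULT_CUTOFF
) -> MethodSummary:
    """False negatives only (good-prognosis calls on deceased patients) per list."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    fn = ((s > cutoff) & (y == 1)).astype(np.int8)
    counts = [int(fn[np.asarray(lst)].sum()) for lst in sample_lists]
    return summarize_runs(counts, method="scoring")


def read_scores_tsv(path: str | Path) -> pd.Series:
    """Read a (patient_id, score) TSV into a Series indexed by patient."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index("patient_id")["score"]
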