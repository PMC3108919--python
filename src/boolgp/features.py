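"""Feature-selection analysis of evolved solutions.

GP performs implicit feature selection: best-of-run trees typically use a
handful of the 70 available features, and a few features recur across many
runs.  This module counts those recurrences (presence per solution, not
terminal multiplicity), summarizes solution sizes, and restricts a dataset
to the top-k most recurrent features for the recursive rerun experiment.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .gp import RunResult
from .preprocessing import BinaryDataset
from .trees import BoolTree

logger = logging.getLogger(__name__)


def feature_frequency(
    results: Sequence[RunResult | BoolTree], gene_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-feature count of solutions containing it at least once.

    Returns a frame with columns (feature, gene_id, solution_count) sorted
    by descending count, ties by original feature index; only features that
    occur in at least one solution appear.
    """
    if len(results) == 0:
        raise ValueError("no results")
    trees = [r.best_tree if isinstance(r, RunResult) else r for r in results]
    counts: dict[int, int] = {}
    for t in trees:
        for f in t.terminals:
            counts[f] = counts.get(f, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {
            "feature": [f for f, _ in rows],
            "gene_id": [
                gene_ids[f] if gene_ids is not None else f"X{f}" for f, _ in rows
            ],
            "solution_count": [c for _, c in rows],
        }
    )


def solution_size_stats(
    results: Sequence[RunResult | BoolTree],
) -> tuple[float, float, float, float, float]:
    """Five-number summary (min, Q1, median, Q3, max) of distinct-terminal counts."""
    if len(results) == 0:
        raise ValueError("no results")
    trees = [r.best_tree if isinstance(r, RunResult) else r for r in results]
    sizes = np.array([len(t.terminals) for t in trees], dtype=float)
    q1, med, q3 = np.percentile(sizes, [25, 50, 75])
    return (float(sizes.min()), float(q1), float(med), float(q3), float(sizes.max()))


def restrict_to_top_k(
    dataset: BinaryDataset, freq: pd.DataFrame, k: int = 10
) -> BinaryDataset:
    """Keep only the k most recurrent feature columns; labels are unchanged.

    Terminal indices of subsequent GP runs refer to the reduced column
    order (most recurrent first).  A tie at the k-th rank is broken by
    original column order and logged.
    """
    nonzero = freq[freq["solution_count"] > 0]
    if k > len(nonzero):
        raise ValueError(
            f"k={k} exceeds the {len(nonzero)} features with nonzero count"
        )
    kth = int(nonzero["solution_count"].iloc[k - 1])
    if (nonzero["solution_count"] == kth).sum() > 1 and k < len(nonzero) and int(
        nonzero["solution_count"].iloc[k]
    ) == kth:
        logger.info(
            "tie at rank %d (count %d); broken by original column order", k, kth
        )
    keep = [int(f) for f in nonzero["feature"].iloc[:k]]
    return BinaryDataset(
        features=dataset.features[:, keep],
        labels=dataset.labels,
        patient_ids=list(dataset.patient_ids),
        gene_ids=[dataset.gene_ids[j] for j in keep],
    )


def write_frequency_tsv(freq: pd.DataFrame, path) -> None:
    freq.to_csv(path, sep="\t", index=False)
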