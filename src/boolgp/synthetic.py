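"""Synthetic cohorts with the statistical structure the analysis assumes.

Real signature/survival cohorts are external data; these generators stand
in for them so every pipeline stage is testable.  A *planted boolean rule*
over a subset of features generates labels, corrupted by independent
label-flip noise — the known ground truth for parameter-recovery checks.
The continuous generator wraps the same binary structure in realistic
plumbing: signed log fold-changes whose sign pattern realizes the binary
features, missing values, and exponential survival times whose hazard
depends on the patient's rule-determined risk group, with independent
exponential censoring.

Default geometry is 148 patients x 70 features with Bernoulli(0.5)
background, matching the balanced-cohort design the classifiers are
compared on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocessing import BinaryDataset, Event, ExpressionCohort
from .trees import BoolTree


@dataclass(frozen=True)
class PlantedRuleSpec:
    """A known boolean rule generating labels with flip noise epsilon."""

    rule: BoolTree
    noise: float = 0.05
    n: int = 148
    p: int = 70
    background: float = 0.5

    def __post_init__(self):
        if not 0 <= self.noise <= 1:
            raise ValueError("noise must be in [0, 1]")
        if not 0 < self.background < 1:
            raise ValueError("background must be in (0, 1)")
        if max(self.rule.terminals) >= self.p:
            raise ValueError("rule terminals must be < p")


@dataclass(frozen=True)
class SurvivalSimSpec:
    """Two-group exponential survival with censoring and expression missingness.

    Hazards are per-year rates; high risk applies to rule-positive
    patients.  ``t_ref`` is the nominal study endpoint used when scaling.
    """

    hazard_high: float = 0.2
    hazard_low: float = 0.02
    censoring_rate: float = 0.05
    missing_rate: float = 0.02
    t_ref: float = 10.3

    def __post_init__(self):
        if self.hazard_high <= 0 or self.hazard_low <= 0:
            raise ValueError("hazards must be positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring rate must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


def generate_binary_cohort(spec: PlantedRuleSpec, seed: int) -> BinaryDataset:
    """i.i.d. Bernoulli features with labels = rule(features) XOR Bernoulli(noise)."""
    rng = np.random.default_rng(seed)
    X = (rng.random((spec.n, spec.p)) < spec.background).astype(np.int8)
    clean = spec.rule.evaluate(X)
    flips = (rng.random(spec.n) < spec.noise).astype(np.int8)
    labels = clean ^ flips
    return BinaryDataset(X, labels)


def generate_continuous_cohort(
    sim: SurvivalSimSpec, rule: PlantedRuleSpec, seed: int
) -> ExpressionCohort:
    """Continuous cohort whose binarization recovers the planted binary features.

    Log ratios are drawn with magnitude |N(0.5, 0.25)| and the sign given by
    the binary feature (positive <-> 1), then entries are masked missing at
    ``missing_rate``.  Survival is exponential with the patient's risk-group
    hazard (high risk = rule-positive), censored by an independent
    exponential clock; the recorded time is the earlier of the two.
    """
    rng = np.random.default_rng(seed)
    binary = generate_binary_cohort(rule, seed=int(rng.integers(2**31)))
    sign = np.where(binary.features == 1, 1.0, -1.0)
    magnitude = np.abs(rng.normal(0.5, 0.25, size=sign.shape)) + 1e-6
    log_ratios = sign * magnitude
    if sim.missing_rate > 0:
        mask = rng.random(sign.shape) < sim.missing_rate
        log_ratios[mask] = np.nan

    risk_high = rule.rule.evaluate(binary.features).astype(bool)
    hazard = np.where(risk_high, sim.hazard_high, sim.hazard_low)
    death_time = rng.exponential(1.0 / hazard)
    if sim.censoring_rate > 0:
        censor_time = rng.exponential(1.0 / sim.censoring_rate, size=rule.n)
    else:
        censor_time = np.full(rule.n, np.inf)
    observed = np.minimum(death_time, censor_time)
    event = [
        Event.DEATH_DISEASE if d <= c else Event.ALIVE
        for d, c in zip(death_time, censor_time)
    ]
    return ExpressionCohort(
        patient_ids=list(binary.patient_ids),
        gene_ids=list(binary.gene_ids),
        log_ratios=log_ratios,
        survival_time=observed,
        event=event,
    )


def make_external_cohort(
    rule: PlantedRuleSpec, gene_dropout: float, seed: int
) -> tuple[BinaryDataset, dict[int, int | None]]:
    """An independent cohort on a platform missing some signature genes.

    Generated under the same planted rule, but each signature feature is
    absent from the external platform with probability ``gene_dropout``.
    Returns the external dataset (surviving columns only) plus the map from
    signature feature index to external column index (None when dropped) —
    trees whose terminals all survive remain applicable with no retraining.
    """
    if not 0 <= gene_dropout < 1:
        raise ValueError("gene_dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)
    full = generate_binary_cohort(rule, seed=int(rng.integers(2**31)))
    present = rng.random(rule.p) >= gene_dropout
    gene_map: dict[int, int | None] = {}
    col = 0
    for j in range(rule.p):
        gene_map[j] = col if present[j] else None
        col += int(present[j])
    external = BinaryDataset(
        features=full.features[:, present],
        labels=full.labels,
        patient_ids=list(full.patient_ids),
        gene_ids=[g for g, keep in zip(full.gene_ids, present) if keep],
    )
    return external, gene_map
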