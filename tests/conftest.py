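import numpy as np
import pytest

from boolgp import BoolTree, GPConfig, PlantedRuleSpec, generate_binary_cohort


@pytest.fixture(scope="session")
def planted_rule() -> BoolTree:
    return BoolTree.parse("(OR X12 (AND X3 X7))")


@pytest.fixture(scope="session")
def planted_ds(planted_rule):
    """148 x 70 planted-rule cohort with 5% label-flip noise."""
    spec = PlantedRuleSpec(rule=planted_rule, noise=0.05, n=148, p=70, background=0.5)
    return generate_binary_cohort(spec, seed=11)


@pytest.fixture(scope="session")
def small_gp_config() -> GPConfig:
    """Reduced search budget for fast unit tests (defaults stay the study's)."""
    return GPConfig(population_size=60, generations=4, init_depth_range=(2, 4))


def brute_force_eval(expr, assignment):
    """Independent per-row interpreter used as the truth-table oracle."""
    if isinstance(expr, (int, np.integer)):
        return bool(assignment[expr])
    op = expr[0]
    if op == "NOT":
        return not brute_force_eval(expr[1], assignment)
    if op == "AND":
        return brute_force_eval(expr[1], assignment) and brute_force_eval(
            expr[2], assignment
        )
    if op == "OR":
        return brute_force_eval(expr[1], assignment) or brute_force_eval(
            expr[2], assignment
        )
    raise AssertionError(op)


def bayes_pattern_bound(X, y) -> int:
    """Brute-force minimum training errors of any deterministic classifier."""
    from collections import defaultdict

    groups = defaultdict(list)
    for row, lab in zip(map(tuple, np.asarray(X)), np.asarray(y)):
        groups[row].append(int(lab))
    return sum(min(sum(g), len(g) - sum(g)) for g in groups.values())
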