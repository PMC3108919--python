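"""Tree-based genetic programming over binary gene-signature features.

The search evolves boolean expression trees that map a patient's binarized
70-gene profile to a survival class (1 = dead of disease before the study
endpoint).  The configuration defaults follow the study design this package
reproduces: a generational algorithm with no elitism, population 500,
5 generations, tournament selection of size 10, subtree crossover with
probability 0.9 and subtree mutation with probability 0.1, ramped
half-and-half initialization.  Fitness is the (optionally class-weighted)
count of misclassified training patients, minimized.

The public surface follows the model/results idiom: build a
:class:`BooleanTreeGP` model from data, call :meth:`~BooleanTreeGP.fit`,
and read estimates off the returned :class:`BooleanTreeGPResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trees import FUNCTIONS, BoolTree, random_tree
from .evaluation import ConfusionMatrix, confusion


@dataclass(frozen=True)
class FitnessWeights:
    """Misclassification weights: fitness = w_fn * FN + w_fp * FP.

    The default (1, 1) counts every error equally.  The sensitivity preset
    (0.9, 0.1) penalizes false negatives — patients who died but were
    predicted to survive, the costliest clinical error — nine times more
    than false positives.
    """

    w_fn: float = 1.0
    w_fp: float = 1.0

    def __post_init__(self):
        if self.w_fn < 0 or self.w_fp < 0:
            raise ValueError("fitness weights must be non-negative")
        if self.w_fn == 0 and self.w_fp == 0:
            raise ValueError("fitness weights cannot both be zero")


#: Preset that rewards sensitivity: false negatives weighted 0.9, false positives 0.1.
SENSITIVITY_WEIGHTS = FitnessWeights(0.9, 0.1)


@dataclass(frozen=True)
class GPConfig:
    """Evolutionary parameters of the boolean-tree GP."""

    population_size: int = 500
    generations: int = 5
    tournament_size: int = 10
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    init_depth_range: tuple[int, int] = (2, 6)
    max_tree_depth: int = 17
    fitness_weights: FitnessWeights = field(default_factory=FitnessWeights)

    def __post_init__(self):
        if min(self.population_size, self.generations, self.tournament_size) < 1:
            raise ValueError("population_size, generations, tournament_size must be >= 1")
        if abs(self.crossover_rate + self.mutation_rate - 1.0) > 1e-9:
            # operators are mutually exclusive per offspring
            raise ValueError("crossover_rate + mutation_rate must equal 1")
        lo, hi = self.init_depth_range
        if not (0 <= lo <= hi <= self.max_tree_depth):
            raise ValueError("invalid init_depth_range")


def evaluate_tree(tree: BoolTree, X: np.ndarray) -> np.ndarray:
    """Predictions in {0,1} of *tree* on each row of the binary matrix *X*."""
    return tree.evaluate(X)


def fitness(
    tree: BoolTree,
    X: np.ndarray,
    y: np.ndarray,
    weights: FitnessWeights = FitnessWeights(),
) -> float:
    """Weighted misclassification count w_fn*FN + w_fp*FP (lower is better)."""
    y = np.asarray(y)
    if len(y) != X.shape[0]:
        raise ValueError("label vector length must match number of rows")
    pred = tree.evaluate(X)
    fn = int(np.sum((y == 1) & (pred == 0)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    return weights.w_fn * fn + weights.w_fp * fp


def init_population(
    config: GPConfig, n_features: int, rng: np.random.Generator
) -> list[BoolTree]:
    """Ramped half-and-half initialization.

    Depths ramp uniformly over ``init_depth_range``; at each depth half the
    trees are built by the ``full`` method and half by ``grow``.
    """
    lo, hi = config.init_depth_range
    depths = list(range(lo, hi + 1))
    pop = []
    for i in range(config.population_size):
        depth = depths[i % len(depths)]
        method = "full" if (i // len(depths)) % 2 == 0 else "grow"
        pop.append(random_tree(rng, n_features, depth, method))
    return pop


def tournament_select(
    population: list[BoolTree],
    fitnesses: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> BoolTree:
    """Sample k individuals with replacement; return one of minimal fitness.

    Ties among the sampled individuals are broken uniformly at random.
    """
    if len(population) == 0:
        raise ValueError("empty population")
    if k > len(population):
        raise ValueError("tournament size exceeds population size")
    idx = rng.integers(0, len(population), size=k)
    sampled = np.asarray(fitnesses)[idx]
    best = sampled.min()
    winners = idx[sampled == best]
    return population[int(winners[rng.integers(len(winners))])]


def subtree_crossover(
    a: BoolTree, b: BoolTree, max_depth: int, rng: np.random.Generator
) -> BoolTree:
    """Replace a uniformly chosen subtree of *a* with one from *b*.

    If the offspring would exceed *max_depth*, point selection is retried up
    to 5 times; after that the first parent is returned unchanged, so the
    depth cap always holds.
    """
    paths_a, paths_b = a.paths(), b.paths()
    for _ in range(5):
        pa = paths_a[rng.integers(len(paths_a))]
        pb = paths_b[rng.integers(len(paths_b))]
        child = a.with_subtree(pa, b.subtree_at(pb))
        if child.depth <= max_depth:
            return child
    return a


def subtree_mutate(
    a: BoolTree,
    max_depth: int,
    rng: np.random.Generator,
    n_features: int | None = None,
    grow_depth: int = 4,
) -> BoolTree:
    """Replace a uniformly chosen subtree with a freshly grown one.

    The replacement is grown to at most ``min(grow_depth, room left under
    the depth cap)``, so the offspring never exceeds *max_depth*.
    """
    if n_features is None:
        n_features = max(a.terminals) + 1
    paths = a.paths()
    p = paths[rng.integers(len(paths))]
    room = max_depth - len(p)
    sub = random_tree(rng, n_features, min(grow_depth, room), "grow")
    return a.with_subtree(p, sub.expr)


@dataclass(frozen=True)
class RunResult:
    """Outcome of one GP run: the best-of-run tree and its bookkeeping."""

    best_tree: BoolTree
    train_fitness: float
    seed: int
    evaluations: int
    test_confusion: ConfusionMatrix | None = None

    @property
    def features_used(self) -> frozenset[int]:
        return self.best_tree.terminals


def run_gp(
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: GPConfig = GPConfig(),
    seed: int = 0,
) -> RunResult:
    """One full generational GP run; deterministic given *seed*.

    Every generation the whole population is evaluated (so the total
    inspection budget is ``population_size * generations``) and then bred
    anew: each offspring comes from subtree crossover of two
    tournament-selected parents (probability ``crossover_rate``) or subtree
    mutation of one (probability ``mutation_rate``).  There is no elitism,
    so the reported solution is the lowest-fitness individual ever seen,
    with ties broken by fewer nodes and then earlier discovery.
    """
    X_train = np.asarray(X_train)
    y_train = np.asarray(y_train)
    if X_train.shape[0] != len(y_train):
        raise ValueError("X_train and y_train length mismatch")
    classes = np.unique(y_train)
    if len(classes) < 2:
        warnings.warn(
            "training labels contain a single class; the evolved tree will be "
            "trivially constant-behaviour",
            UserWarning,
            stacklevel=2,
        )
    n_features = X_train.shape[1]
    rng = np.random.default_rng(seed)
    w = config.fitness_weights

    pop = init_population(config, n_features, rng)
    best_tree: BoolTree | None = None
    best_fit = np.inf
    evaluations = 0

    for gen in range(config.generations):
        fits = np.array([fitness(t, X_train, y_train, w) for t in pop])
        evaluations += len(pop)
        for t, f in zip(pop, fits):
            if f < best_fit or (f == best_fit and t.n_nodes < best_tree.n_nodes):
                best_tree, best_fit = t, f
        if gen == config.generations - 1:
            break
        new_pop = []
        for _ in range(config.population_size):
            if rng.random() < config.crossover_rate:
                pa = tournament_select(pop, fits, config.tournament_size, rng)
                pb = tournament_select(pop, fits, config.tournament_size, rng)
                child = subtree_crossover(pa, pb, config.max_tree_depth, rng)
            else:
                pa = tournament_select(pop, fits, config.tournament_size, rng)
                child = subtree_mutate(pa, config.max_tree_depth, rng, n_features)
            new_pop.append(child)
        pop = new_pop

    return RunResult(
        best_tree=best_tree,
        train_fitness=float(best_fit),
        seed=seed,
        evaluations=evaluations,
    )


class BooleanTreeGP:
    """Boolean-tree GP classifier model over a binary feature matrix.

    Parameters
    ----------
    X : (n, p) array of {0,1}
        Binarized expression features, one patient per row.
    y : (n,) array of {0,1}
        Survival class (1 = dead of disease before the endpoint).
    config : GPConfig, optional
        Evolutionary parameters; study defaults if omitted.
    feature_names : sequence of str, optional
        Gene identifiers for the columns, used in summaries.

    Examples
    --------
    >>> model = BooleanTreeGP(X, y)
    >>> res = model.fit(seed=1)
    >>> res.best_tree.to_sexpr()
    '(OR X12 (AND X3 X7))'
    """

    def __init__(self, X, y, config: GPConfig | None = None, feature_names=None):
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != len(y):
            raise ValueError("X must be n x p with len(y) == n")
        if not np.isin(X, (0, 1)).all() or not np.isin(y, (0, 1)).all():
            raise ValueError("X and y must be binary")
        self.X = X.astype(np.int8)
        self.y = y.astype(np.int8)
        self.config = config or GPConfig()
        if feature_names is not None and len(feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length mismatch")
        self.feature_names = list(feature_names) if feature_names is not None else None

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_col: str = "label", config: GPConfig | None = None
    ) -> "BooleanTreeGP":
        """Build the model from a binary matrix table whose last column is the label."""
        y = df[label_col].to_numpy()
        Xdf = df.drop(columns=[label_col])
        return cls(Xdf.to_numpy(), y, config=config, feature_names=list(Xdf.columns))

    def fit(self, seed: int = 0) -> "BooleanTreeGPResults":
        """Run the evolutionary search once and wrap the best-of-run solution."""
        run = run_gp(self.X, self.y, self.config, seed)
        return BooleanTreeGPResults(self, run)


class BooleanTreeGPResults:
    """Fitted results of one GP run: the best evolved tree plus diagnostics."""

    def __init__(self, model: BooleanTreeGP, run: RunResult):
        self.model = model
        self.run = run

    @property
    def best_tree(self) -> BoolTree:
        return self.run.best_tree

    @property
    def train_fitness(self) -> float:
        return self.run.train_fitness

    @property
    def features_used(self) -> frozenset[int]:
        return self.run.features_used

    @property
    def evaluations(self) -> int:
        return self.run.evaluations

    def predict(self, X) -> np.ndarray:
        return self.best_tree.evaluate(np.asarray(X))

    def confusion(self, X, y) -> ConfusionMatrix:
        return confusion(self.predict(X), y)

    def summary(self) -> str:
        cfg = self.model.config
        names = self.model.feature_names
        used = sorted(self.features_used)
        feats = ", ".join(names[i] if names else f"X{i}" for i in used)
        lines = [
            "Boolean-tree GP results",
            "=" * 55,
            f"population size      {cfg.population_size}",
            f"generations          {cfg.generations}",
            f"tournament size      {cfg.tournament_size}",
            f"crossover/mutation   {cfg.crossover_rate}/{cfg.mutation_rate}",
            f"fitness weights      FN={cfg.fitness_weights.w_fn} FP={cfg.fitness_weights.w_fp}",
            f"seed                 {self.run.seed}",
            f"tree inspections     {self.evaluations}",
            "-" * 55,
            f"train fitness        {self.train_fitness:g}",
            f"features used        {len(used)}: {feats}",
            f"best tree            {self.best_tree.to_sexpr()}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<BooleanTreeGPResults fitness={self.train_fitness:g} "
            f"tree={self.best_tree.to_sexpr()}>"
        )
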