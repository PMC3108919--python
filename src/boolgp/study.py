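"""Resampled comparison study: every classifier on identical train/test splits.

The experiment design: fix a binary dataset (the matrix H), draw ``n_runs``
independent 70/30 train/test partitions once, and run every method on the
same partitions so per-run error counts are paired.  Per method the study
reports the best (lowest) and mean test error with its SEM, for both total
misclassifications and false negatives; across methods it reports a one-way
ANOVA over all method groups and pairwise two-sided Student t-tests of GP
against each comparator.  GP runs additionally feed the feature-recurrence
table and the optional top-k feature-restricted rerun.

Usage follows the model/results idiom::

    study = SignatureStudy(dataset, methods=["gp", "svm_poly2"], n_runs=50)
    res = study.fit(master_seed=42)
    print(res.summary())
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparators, features
from .evaluation import (
    MethodSummary,
    confusion,
    one_way_anova,
    summarize_runs,
    two_tailed_t_test,
)
from .gp import GPConfig, FitnessWeights, SENSITIVITY_WEIGHTS, RunResult, run_gp
from .preprocessing import (
    BinaryDataset,
    SplitPlan,
    make_binary_dataset,
    make_splits,
    read_expression_tsv,
    select_balanced_endpoint,
    write_binary_tsv,
)
from .scoring import DEFAULT_CUTOFF, score_errors
from .synthetic import PlantedRuleSpec, generate_binary_cohort
from .trees import BoolTree

logger = logging.getLogger(__name__)

#: CLI-friendly aliases for method names.
ALIASES = {
    "gp": "gp",
    "gp_weighted": "gp_weighted",
    "svm1": "svm_poly1",
    "svm2": "svm_poly2",
    "svm3": "svm_poly3",
    "svm_poly1": "svm_poly1",
    "svm_poly2": "svm_poly2",
    "svm_poly3": "svm_poly3",
    "mlp": "mlp",
    "rf": "random_forest",
    "random_forest": "random_forest",
    "scoring": "scoring",
}


def _run_seed(master_seed: int, method: str, run_index: int) -> int:
    """Named per-stage substream: an int32 seed from (master_seed, method, run)."""
    tag = int.from_bytes(method.encode()[:4].ljust(4, b"\0"), "little")
    ss = np.random.SeedSequence([master_seed, tag, run_index])
    return int(ss.generate_state(1)[0] % (2**31))


class SignatureStudy:
    """Paired comparison of classifiers on shared resampled splits.

    Parameters
    ----------
    dataset : BinaryDataset
        The binary matrix H with outcome labels.
    methods : list of str
        Any of gp, gp_weighted, svm_poly1/2/3 (svm1..3), mlp,
        random_forest (rf), scoring.  The scoring baseline requires
        ``scores``.
    n_runs, train_fraction
        Resampling design; defaults 50 runs at 70/30.
    gp_config : GPConfig, optional
        Parameters for the GP runs (study defaults if omitted).
    scores : array-like, optional
        Per-patient prognosis scores for the scoring baseline.
    """

    def __init__(
        self,
        dataset: BinaryDataset,
        methods: list[str],
        n_runs: int = 50,
        train_fraction: float = 0.7,
        gp_config: GPConfig | None = None,
        scores=None,
        score_cutoff: float = DEFAULT_CUTOFF,
    ):
        if not methods:
            raise ValueError("methods list must be non-empty")
        self.dataset = dataset
        self.methods = [ALIASES[m] for m in methods]
        self.n_runs = n_runs
        self.train_fraction = train_fraction
        self.gp_config = gp_config or GPConfig()
        self.scores = None if scores is None else np.asarray(scores, dtype=float)
        self.score_cutoff = score_cutoff
        if "scoring" in self.methods and self.scores is None:
            raise ValueError("the scoring baseline requires per-patient scores")

    def fit(self, master_seed: int = 0, plan: SplitPlan | None = None) -> "StudyResults":
        """Run every method on a shared split plan; reproducible from the seed."""
        ds = self.dataset
        if plan is None:
            plan = make_splits(ds.n_patients, self.train_fraction, self.n_runs, master_seed)
        X, y = ds.features, ds.labels
        errors: dict[str, list[int]] = {m: [] for m in self.methods}
        false_negatives: dict[str, list[int]] = {m: [] for m in self.methods}
        gp_runs: dict[str, list[RunResult]] = {
            m: [] for m in self.methods if m.startswith("gp")
        }

        for r, (train, test) in enumerate(plan.runs):
            train = np.asarray(train)
            test = np.asarray(test)
            for m in self.methods:
                if m.startswith("gp"):
                    cfg = self.gp_config
                    if m == "gp_weighted":
                        cfg = replace(cfg, fitness_weights=SENSITIVITY_WEIGHTS)
                    run = run_gp(X[train], y[train], cfg, _run_seed(master_seed, m, r))
                    cm = confusion(run.best_tree.evaluate(X[test]), y[test])
                    gp_runs[m].append(
                        RunResult(
                            run.best_tree,
                            run.train_fitness,
                            run.seed,
                            run.evaluations,
                            cm,
                        )
                    )
                elif m == "scoring":
                    wrong = score_errors(self.scores, y, self.score_cutoff)
                    errors[m].append(int(wrong[test].sum()))
                    fn = (self.scores > self.score_cutoff) & (y == 1)
                    false_negatives[m].append(int(fn[test].sum()))
                    continue
                else:
                    model = comparators.train_comparator(
                        comparators.ComparatorSpec(m),
                        X[train],
                        y[train],
                        _run_seed(master_seed, m, r),
                    )
                    cm = confusion(comparators.predict_comparator(model, X[test]), y[test])
                if m != "scoring":
                    errors[m].append(cm.errors)
                    false_negatives[m].append(cm.fn)
                logger.info(
                    "run %d method %s: test errors %d (fn %d)",
                    r,
                    m,
                    errors[m][-1],
                    false_negatives[m][-1],
                )
        return StudyResults(
            study=self,
            plan=plan,
            master_seed=master_seed,
            errors=errors,
            false_negatives=false_negatives,
            gp_runs=gp_runs,
        )


class StudyResults:
    """Per-run error tables, summary statistics and feature analysis."""

    def __init__(self, study, plan, master_seed, errors, false_negatives, gp_runs):
        self.study = study
        self.plan = plan
        self.master_seed = master_seed
        self.errors = errors
        self.false_negatives = false_negatives
        self.gp_runs = gp_runs

    # -- tables -------------------------------------------------------------

    def error_table(self, metric: str = "errors") -> pd.DataFrame:
        """Per-run error counts, one column per method."""
        src = self.errors if metric == "errors" else self.false_negatives
        return pd.DataFrame(src)

    def summaries(self, metric: str = "errors") -> dict[str, MethodSummary]:
        src = self.errors if metric == "errors" else self.false_negatives
        return {m: summarize_runs(v, method=m) for m, v in src.items()}

    def summary_table(self, metric: str = "errors") -> pd.DataFrame:
        """Best / mean / SEM per method, the comparison-table layout."""
        rows = []
        for m, s in self.summaries(metric).items():
            rows.append({"method": m, "best": s.best, "mean": s.mean, "sem": s.sem})
        return pd.DataFrame(rows).set_index("method")

    # -- statistics ---------------------------------------------------------

    def anova_p(self, metric: str = "errors") -> float:
        """One-way ANOVA over the per-run error counts of all methods run."""
        src = self.errors if metric == "errors" else self.false_negatives
        return one_way_anova(list(src.values()))

    def pairwise_vs(self, reference: str = "gp", metric: str = "errors") -> dict[str, float]:
        """Two-sided Student t-test p-values of the reference method vs each other."""
        src = self.errors if metric == "errors" else self.false_negatives
        if reference not in src:
            raise ValueError(f"reference method {reference!r} was not run")
        ref = src[reference]
        return {
            m: two_tailed_t_test(ref, v) for m, v in src.items() if m != reference
        }

    # -- feature analysis ---------------------------------------------------

    def feature_frequency(self, method: str = "gp") -> pd.DataFrame:
        return features.feature_frequency(
            self.gp_runs[method], gene_ids=self.study.dataset.gene_ids
        )

    def solution_size_stats(self, method: str = "gp"):
        return features.solution_size_stats(self.gp_runs[method])

    def best_trees(self, method: str = "gp") -> list[BoolTree]:
        return [r.best_tree for r in self.gp_runs[method]]

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Signature comparison study",
            "=" * 60,
            f"patients {self.study.dataset.n_patients}, "
            f"features {self.study.dataset.n_features}, "
            f"runs {self.plan.n_runs}, "
            f"test size {len(self.plan.runs[0][1])}",
            "",
            "Test-set misclassifications:",
            self.summary_table("errors").to_string(float_format=lambda v: f"{v:.2f}"),
            "",
            "Test-set false negatives:",
            self.summary_table("fn").to_string(float_format=lambda v: f"{v:.2f}"),
        ]
        if len(self.errors) >= 2:
            lines += ["", f"ANOVA P = {self.anova_p():.3g}"]
            if "gp" in self.errors:
                for m, p in self.pairwise_vs("gp").items():
                    lines.append(f"gp vs. {m}  P = {p:.3g}")
        if "gp" in self.gp_runs and self.gp_runs["gp"]:
            mn, q1, med, q3, mx = self.solution_size_stats("gp")
            lines += [
                "",
                f"GP solution sizes (distinct features): min {mn:.0f}, "
                f"Q1 {q1:.1f}, median {med:.1f}, Q3 {q3:.1f}, max {mx:.0f}",
            ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """Machine-readable, deterministically ordered summary."""
        out = {
            "master_seed": self.master_seed,
            "n_runs": self.plan.n_runs,
            "n_patients": self.study.dataset.n_patients,
            "n_features": self.study.dataset.n_features,
            "test_size": len(self.plan.runs[0][1]),
            "errors": {m: list(map(float, v)) for m, v in sorted(self.errors.items())},
            "false_negatives": {
                m: list(map(float, v)) for m, v in sorted(self.false_negatives.items())
            },
            "summary": {
                m: {"best": s.best, "mean": s.mean, "sem": s.sem}
                for m, s in sorted(self.summaries().items())
            },
        }
        if len(self.errors) >= 2:
            out["anova_p"] = self.anova_p()
            out["anova_groups"] = sorted(self.errors)
            if "gp" in self.errors:
                out["pairwise_p_vs_gp"] = dict(sorted(self.pairwise_vs("gp").items()))
        if "gp" in self.gp_runs and self.gp_runs["gp"]:
            out["gp_trees"] = [t.to_sexpr() for t in self.best_trees("gp")]
        return out

    def save(self, outdir: str | Path) -> None:
        """Write the report bundle: TSV tables, run manifests, trees, JSON summary."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for metric, stem in (("errors", "errors"), ("fn", "false_negatives")):
            self.summary_table(metric).to_csv(outdir / f"summary_{stem}.tsv", sep="\t")
            self.error_table(metric).to_csv(
                outdir / f"per_run_{stem}.tsv", sep="\t", index_label="run"
            )
        if len(self.errors) >= 2 and "gp" in self.errors:
            stats = pd.DataFrame(
                {
                    "comparison": [f"gp vs. {m}" for m in self.pairwise_vs("gp")],
                    "p_value": list(self.pairwise_vs("gp").values()),
                }
            )
            stats.to_csv(outdir / "pairwise_tests.tsv", sep="\t", index=False)
        for m, runs in self.gp_runs.items():
            if not runs:
                continue
            self.feature_frequency(m).to_csv(
                outdir / f"feature_frequency_{m}.tsv", sep="\t", index=False
            )
            manifest = pd.DataFrame(
                {
                    "run": range(len(runs)),
                    "seed": [r.seed for r in runs],
                    "train_fitness": [r.train_fitness for r in runs],
                    "test_errors": [r.test_confusion.errors for r in runs],
                    "test_fn": [r.test_confusion.fn for r in runs],
                    "features_used": [
                        ",".join(map(str, sorted(r.features_used))) for r in runs
                    ],
                }
            )
            manifest.to_csv(outdir / f"run_manifest_{m}.tsv", sep="\t", index=False)
            with open(outdir / f"trees_{m}.txt", "w") as fh:
                for r in runs:
                    fh.write(r.best_tree.to_sexpr() + "\n")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# experiment configuration & one-shot driver

@dataclass
class ExperimentConfig:
    """Declarative description of a full study, loadable from YAML.

    Either ``expression_path``+``clinical_path`` (real cohort files) or
    ``synthetic`` (a planted-rule spec) provides the data.  ``t_end`` may be
    a number of years or "balanced" to pick the class-balancing endpoint.
    """

    methods: list[str] = field(default_factory=lambda: ["gp", "svm_poly2"])
    n_runs: int = 50
    train_fraction: float = 0.7
    master_seed: int = 0
    t_end: float | str = "balanced"
    expression_path: str | None = None
    clinical_path: str | None = None
    synthetic: dict | None = None
    gp: dict = field(default_factory=dict)
    fitness_weights: tuple[float, float] = (1.0, 1.0)
    top_k_rerun: int | None = None
    output_dir: str = "study_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def gp_config(self) -> GPConfig:
        w = FitnessWeights(*self.fitness_weights)
        return GPConfig(**self.gp, fitness_weights=w)

    def load_dataset(self) -> BinaryDataset:
        if self.synthetic is not None:
            syn = dict(self.synthetic)
            rule = BoolTree.parse(syn.pop("rule"))
            spec = PlantedRuleSpec(rule=rule, **syn)
            return generate_binary_cohort(spec, seed=_run_seed(self.master_seed, "data", 0))
        if not (self.expression_path and self.clinical_path):
            raise ValueError("config needs either synthetic spec or cohort file paths")
        cohort = read_expression_tsv(self.expression_path, self.clinical_path)
        t_end = (
            select_balanced_endpoint(cohort)
            if self.t_end == "balanced"
            else float(self.t_end)
        )
        return make_binary_dataset(cohort, t_end)


def run_experiment(config: ExperimentConfig) -> StudyResults:
    """Preprocess, resample, run all methods, write the report bundle.

    Fully reproducible from ``config.master_seed``; the optional top-k
    rerun reuses a fresh split plan on the restricted dataset and writes a
    second bundle under ``<output_dir>/top_k``.
    """
    dataset = config.load_dataset()
    study = SignatureStudy(
        dataset,
        methods=config.methods,
        n_runs=config.n_runs,
        train_fraction=config.train_fraction,
        gp_config=config.gp_config(),
    )
    results = study.fit(master_seed=config.master_seed)
    outdir = Path(config.output_dir)
    results.save(outdir)
    write_binary_tsv(dataset, outdir / "H.tsv")

    if config.top_k_rerun:
        if "gp" not in results.gp_runs or not results.gp_runs["gp"]:
            raise ValueError("top-k rerun requires the gp method")
        freq = results.feature_frequency("gp")
        reduced = features.restrict_to_top_k(dataset, freq, k=config.top_k_rerun)
        substudy = SignatureStudy(
            reduced,
            methods=config.methods,
            n_runs=config.n_runs,
            train_fraction=config.train_fraction,
            gp_config=config.gp_config(),
        )
        # same split plan: the restriction keeps all patients
        subresults = substudy.fit(master_seed=config.master_seed, plan=results.plan)
        subresults.save(outdir / "top_k")
    return results
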