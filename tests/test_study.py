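"""Study orchestration, report bundle, config handling and the CLI."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from boolgp import (
    ExperimentConfig,
    GPConfig,
    SignatureStudy,
    run_experiment,
)
from boolgp.cli import main as cli_main

SMALL_GP = {"population_size": 50, "generations": 3, "init_depth_range": (2, 4)}


@pytest.fixture(scope="module")
def small_results(planted_ds):
    study = SignatureStudy(
        planted_ds,
        methods=["gp", "svm2"],
        n_runs=4,
        gp_config=GPConfig(**SMALL_GP),
    )
    return study.fit(master_seed=7)


class TestStudy:
    def test_error_tables_have_method_per_run_shape(self, small_results):
        tab = small_results.error_table()
        assert tab.shape == (4, 2)
        assert set(tab.columns) == {"gp", "svm_poly2"}
        fn = small_results.error_table("fn")
        assert (fn.to_numpy() <= tab.to_numpy()).all()

    def test_split_plan_shared_across_methods(self, small_results):
        # one plan object reused; per-run test sets identical by construction
        assert small_results.plan.n_runs == 4
        for train, test in small_results.plan.runs:
            assert set(train) & set(test) == set()

    def test_summary_statistics_present(self, small_results):
        text = small_results.summary()
        assert "ANOVA" in text and "gp vs. svm_poly2" in text
        assert 0 <= small_results.anova_p() <= 1
        p = small_results.pairwise_vs("gp")["svm_poly2"]
        assert 0 <= p <= 1

    def test_repeat_fit_is_deterministic(self, planted_ds):
        study = SignatureStudy(
            planted_ds, methods=["gp"], n_runs=2, gp_config=GPConfig(**SMALL_GP)
        )
        a = study.fit(master_seed=3).to_dict()
        b = study.fit(master_seed=3).to_dict()
        assert a == b

    def test_scoring_method_requires_scores(self, planted_ds):
        with pytest.raises(ValueError):
            SignatureStudy(planted_ds, methods=["scoring"], n_runs=2)

    def test_scoring_method_runs_with_scores(self, planted_ds):
        rng = np.random.default_rng(0)
        # informative synthetic scores: survivors score high
        scores = np.where(planted_ds.labels == 0, 0.6, 0.1) + rng.normal(0, 0.2, 148)
        study = SignatureStudy(
            planted_ds, methods=["scoring"], n_runs=3, scores=scores
        )
        res = study.fit(master_seed=1)
        assert len(res.errors["scoring"]) == 3

    def test_save_writes_report_bundle(self, small_results, tmp_path):
        small_results.save(tmp_path)
        expected = [
            "summary_errors.tsv",
            "summary_false_negatives.tsv",
            "per_run_errors.tsv",
            "pairwise_tests.tsv",
            "feature_frequency_gp.tsv",
            "run_manifest_gp.tsv",
            "trees_gp.txt",
            "summary.json",
        ]
        for name in expected:
            assert (tmp_path / name).exists(), name
        payload = json.loads((tmp_path / "summary.json").read_text())
        assert payload["test_size"] == 44


class TestExperimentConfig:
    def test_yaml_round_trip_and_unknown_keys(self, tmp_path):
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(
            yaml.safe_dump(
                {
                    "methods": ["gp"],
                    "n_runs": 2,
                    "master_seed": 5,
                    "synthetic": {"rule": "(AND X1 X2)", "n": 40, "p": 6, "noise": 0.0},
                    "gp": SMALL_GP,
                }
            )
        )
        cfg = ExperimentConfig.from_yaml(cfg_path)
        assert cfg.n_runs == 2 and cfg.master_seed == 5
        bad = tmp_path / "bad.yaml"
        bad.write_text("bogus_key: 1\n")
        with pytest.raises(ValueError, match="bogus_key"):
            ExperimentConfig.from_yaml(bad)

    def test_run_experiment_writes_bundle(self, tmp_path):
        cfg = ExperimentConfig(
            methods=["gp"],
            n_runs=2,
            master_seed=4,
            synthetic={"rule": "(AND X1 X2)", "n": 40, "p": 6, "noise": 0.0},
            gp=SMALL_GP,
            output_dir=str(tmp_path / "out"),
        )
        res = run_experiment(cfg)
        assert (tmp_path / "out" / "summary.json").exists()
        assert (tmp_path / "out" / "H.tsv").exists()
        assert len(res.errors["gp"]) == 2

    def test_top_k_rerun_writes_sub_bundle(self, tmp_path):
        cfg = ExperimentConfig(
            methods=["gp"],
            n_runs=3,
            master_seed=4,
            synthetic={"rule": "(AND X1 X2)", "n": 60, "p": 8, "noise": 0.0},
            gp=SMALL_GP,
            top_k_rerun=2,
            output_dir=str(tmp_path / "out"),
        )
        run_experiment(cfg)
        assert (tmp_path / "out" / "top_k" / "summary.json").exists()


class TestCLI:
    def test_simulate_then_gp_run_then_compare(self, tmp_path):
        runner = CliRunner()
        h = tmp_path / "H.tsv"
        r = runner.invoke(
            cli_main,
            [
                "simulate", "--rule", "(AND X1 X2)", "--n", "50", "--p", "6",
                "--noise", "0.0", "--seed", "1", "--out", str(h),
            ],
        )
        assert r.exit_code == 0, r.output
        r = runner.invoke(
            cli_main,
            [
                "gp-run", "--data", str(h), "--pop", "50", "--gens", "3",
                "--seed", "2", "--out", str(tmp_path / "gp"),
            ],
        )
        assert r.exit_code == 0, r.output
        assert "best tree" in r.output
        r = runner.invoke(
            cli_main,
            [
                "compare", "--data", str(h), "--methods", "gp,svm1",
                "--runs", "2", "--seed", "3", "--out", str(tmp_path / "cmp"),
            ],
        )
        assert r.exit_code == 0, r.output
        assert (tmp_path / "cmp" / "summary.json").exists()

    def test_features_subcommand(self, tmp_path):
        trees = tmp_path / "trees.txt"
        trees.write_text("(AND X1 X2)\nX1\n(NOT X1)\n")
        runner = CliRunner()
        r = runner.invoke(
            cli_main,
            ["features", "--trees", str(trees), "--out", str(tmp_path / "freq.tsv")],
        )
        assert r.exit_code == 0, r.output
        assert (tmp_path / "freq.tsv").exists()

    def test_full_study_from_config(self, tmp_path):
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(
            yaml.safe_dump(
                {
                    "methods": ["gp"],
                    "n_runs": 2,
                    "master_seed": 1,
                    "synthetic": {"rule": "(AND X1 X2)", "n": 40, "p": 6, "noise": 0.0},
                    "gp": SMALL_GP,
                    "output_dir": str(tmp_path / "out"),
                }
            )
        )
        r = CliRunner().invoke(cli_main, ["full-study", "--config", str(cfg_path)])
        assert r.exit_code == 0, r.output
        assert "report bundle" in r.output

    def test_stage_failure_sets_nonzero_exit(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("patient_id\tG1\tlabel\nP1\t2\t1\n")  # non-binary entry
        r = CliRunner().invoke(
            cli_main,
            ["compare", "--data", str(bad), "--methods", "gp", "--runs", "2",
             "--out", str(tmp_path / "x")],
        )
        assert r.exit_code != 0
        assert "[compare]" in r.output
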