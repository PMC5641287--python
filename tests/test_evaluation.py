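import numpy as np
import pandas as pd
import pytest

from cdpop import evaluation as ev
from cdpop.evaluation import (
    ScenarioConfig,
    expected_vs_observed_summary,
    observed_accuracy,
    run_scenario,
)


class TestObservedAccuracy:
    def test_equals_raw_correlation_at_full_heritability(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        r = float(np.corrcoef(x, y)[0, 1])
        assert observed_accuracy(x, y, 1.0) == pytest.approx(r)

    def test_heritability_rescaling(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        assert observed_accuracy(x, y, 0.25) == pytest.approx(
            2.0 * observed_accuracy(x, y, 1.0)
        )

    def test_negative_correlation_is_preserved(self):
        x = np.arange(10.0)
        y = -x + np.random.default_rng(2).normal(scale=0.1, size=10)
        assert observed_accuracy(x, y, 0.5) < 0.0

    def test_rescaled_accuracy_may_exceed_one(self):
        x = np.arange(10.0)
        assert observed_accuracy(x, x, 0.25) == pytest.approx(2.0)

    @pytest.mark.parametrize("h2", [0.0, -0.5])
    def test_nonpositive_h2_rejected(self, h2):
        with pytest.raises(ValueError):
            observed_accuracy([1, 2, 3], [1, 2, 4], h2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            observed_accuracy([1, 1, 1], [1, 2, 3], 0.5)

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            observed_accuracy([1, 2], [1, 2], 0.5)


class TestScenarioConfig:
    def test_lambda_policy_defaults(self):
        assert ScenarioConfig("S1").lambda_policy == "from_h2_table"
        assert ScenarioConfig("OT1").lambda_policy == "fixed_1"

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            ScenarioConfig("S9")


class TestSScenarios:
    def test_s1_covers_all_ordered_family_pairs(self, small_dataset):
        data, _ = small_dataset
        report = run_scenario(data, ScenarioConfig("S1", seed=1))
        n_fam = len(data.families())
        assert len(report) == n_fam * (n_fam - 1)
        assert (report.predicted_family != report.calibration).all()
        assert (report.lam > 0).all()
        assert report.expected_accuracy.between(0, 1).all()

    def test_s2_uses_all_other_families(self, small_dataset):
        data, _ = small_dataset
        report = run_scenario(data, ScenarioConfig("S2", seed=1))
        fams = data.families()
        assert len(report) == len(fams)
        for _, row in report.iterrows():
            expected_size = sum(
                len(ids) for f, ids in fams.items() if f != row.predicted_family
            )
            assert row["size"] == expected_size

    def test_s3_reports_families_and_pooled_targets(self, small_dataset):
        data, _ = small_dataset
        report = run_scenario(data, ScenarioConfig("S3", seed=1))
        assert set(report.predicted_family) == set(data.families()) | {"ALL"}
        pooled = report[report.predicted_family == "ALL"]
        assert (pooled.scope == "global").all()
        assert (pooled.criterion == "cdallnam").all()

    def test_s3_without_panel_rejected(self, small_dataset):
        data, _ = small_dataset
        no_panel = ev.PredictionDataset(
            data.kinship, data.family_of, data.phenotypes, data.h2, None
        )
        with pytest.raises(ValueError, match="panel"):
            run_scenario(no_panel, ScenarioConfig("S3", seed=1))

    def test_s1_reml_policy_runs(self, small_dataset):
        data, _ = small_dataset
        report = run_scenario(
            data, ScenarioConfig("S1", lambda_policy="reml", seed=1)
        )
        assert (report.lam > 0).all()


@pytest.fixture(scope="module")
def ot_config_kwargs():
    """Small search effort: the OT tests check structure, not optimality."""
    return dict(
        n_random_reps=2, optimizer_max_iterations=60,
        optimizer_patience=25, optimizer_restarts=1,
    )


class TestOtScenarios:
    def test_ot1_sizes_accepted_verbatim_and_lambda_one(self, small_dataset,
                                                        ot_config_kwargs):
        data, _ = small_dataset
        report = run_scenario(data, ScenarioConfig(
            "OT1", calibration_sizes=[8, 13], seed=1,
            predicted_families=["F01"], samplers=["cdpop", "random"],
            **ot_config_kwargs,
        ))
        assert sorted(report["size"].unique()) == [8, 13]
        assert (report.lam == 1.0).all()
        assert set(report.sampler) == {"cdpop", "random"}

    def test_ot1_criterion_values_recorded_for_optimized_sets(
            self, small_dataset, ot_config_kwargs):
        data, _ = small_dataset
        report = run_scenario(data, ScenarioConfig(
            "OT1", calibration_sizes=[10], seed=2,
            predicted_families=["F02"], samplers=["cdpop", "crit_kin"],
            **ot_config_kwargs,
        ))
        assert report.criterion_value.notna().all()
        assert report[report.sampler == "cdpop"].criterion_value.between(0, 1).all()

    def test_ot3_reports_within_and_global_scopes(self, small_dataset,
                                                  ot_config_kwargs):
        data, _ = small_dataset
        report = run_scenario(data, ScenarioConfig(
            "OT3", calibration_sizes=[12], seed=3,
            samplers=["cdpop_mean", "stratified_equal", "random"],
            **ot_config_kwargs,
        ))
        assert set(report.scope) == {"within", "global"}
        global_rows = report[report.scope == "global"]
        assert (global_rows.predicted_family == "ALL").all()
        per_cell = report.groupby(["sampler", "replicate"]).size()
        assert (per_cell == len(data.families()) + 1).all()

    def test_ot4_samples_from_panel(self, small_dataset, ot_config_kwargs):
        data, _ = small_dataset
        report = run_scenario(data, ScenarioConfig(
            "OT4", calibration_sizes=[10], seed=4,
            samplers=["cdallnam", "random"], **ot_config_kwargs,
        ))
        assert len(report) > 0
        assert (report.lam == 1.0).all()

    def test_oversized_calibration_sets_are_skipped(self, small_dataset,
                                                    ot_config_kwargs):
        data, _ = small_dataset
        report = run_scenario(data, ScenarioConfig(
            "OT1", calibration_sizes=[10_000], seed=5,
            predicted_families=["F01"], samplers=["random"],
            **ot_config_kwargs,
        ))
        assert report.empty

    def test_reproducible_from_seed(self, small_dataset, ot_config_kwargs):
        data, _ = small_dataset
        cfg = dict(
            calibration_sizes=[9], seed=6, predicted_families=["F01"],
            samplers=["cdpop", "random"], **ot_config_kwargs,
        )
        a = run_scenario(data, ScenarioConfig("OT1", **cfg))
        b = run_scenario(data, ScenarioConfig("OT1", **cfg))
        pd.testing.assert_frame_equal(a, b)


class TestSummary:
    def test_perfect_agreement_gives_unit_line(self):
        report = pd.DataFrame({
            "predicted_family": ["A"] * 4 + ["B"] * 4,
            "expected_accuracy": [0.1, 0.2, 0.3, 0.4] * 2,
            "observed_accuracy": [0.1, 0.2, 0.3, 0.4] * 2,
        })
        out = expected_vs_observed_summary(report)
        pooled = out[out.group == "pooled"].iloc[0]
        assert pooled.correlation == pytest.approx(1.0)
        assert pooled.slope == pytest.approx(1.0)
        assert pooled.intercept == pytest.approx(0.0, abs=1e-12)
        assert set(out.group) == {"A", "B", "pooled"}

    def test_constant_expected_group_is_skipped(self):
        report = pd.DataFrame({
            "predicted_family": ["A"] * 4,
            "expected_accuracy": [0.3] * 4,
            "observed_accuracy": [0.1, 0.2, 0.3, 0.4],
        })
        out = expected_vs_observed_summary(report)
        assert out.empty

    def test_pooled_matches_direct_recomputation(self, small_dataset):
        data, _ = small_dataset
        report = run_scenario(data, ScenarioConfig("S1", seed=1))
        out = expected_vs_observed_summary(report)
        pooled = out[out.group == "pooled"].iloc[0]
        direct = np.corrcoef(
            report.expected_accuracy, report.observed_accuracy
        )[0, 1]
        assert pooled.correlation == pytest.approx(float(direct), abs=1e-12)
        assert pooled.n_pairs == len(report)


class TestPanelCalibration:
    def test_global_accuracy_exceeds_within_family_mean(self):
        """With panel calibration of a NAM whose families are well
        differentiated, predicting the population as a whole (family
        means included) is easier than resolving within-family
        Mendelian-sampling deviations, so the pooled (global) accuracy
        should exceed the mean within-family accuracy."""
        wins = []
        for rep in range(20):
            data, _ = ev.simulate_prediction_dataset(
                family_sizes=[30] * 6, n_panel=40, n_ancestors=12,
                seed=9000 + rep,
            )
            report = run_scenario(data, ScenarioConfig("S3", seed=rep))
            global_acc = float(
                report[report.scope == "global"].observed_accuracy.iloc[0]
            )
            within_mean = float(
                report[report.scope == "within"].observed_accuracy.mean()
            )
            wins.append(global_acc >= within_mean)
        assert np.mean(wins) >= 0.8


class TestSimulatedDataset:
    def test_panel_contains_parents_and_extras(self, small_dataset):
        data, pop = small_dataset
        assert len(data.panel_ids) == 25
        assert sum(i.startswith("parent") for i in data.panel_ids) == 4
        assert set(data.h2) >= {"F01", "F02", "F03", "pooled", "panel"}

    def test_phenotypes_cover_nam_and_panel(self, small_dataset):
        data, _ = small_dataset
        covered = set(data.phenotypes.index)
        assert set(data.kinship.individual_ids) <= covered


class TestCli:
    def test_simulate_kinship_scenario_evaluate_pipeline(self, tmp_path):
        from click.testing import CliRunner

        from cdpop.cli import main

        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        result = runner.invoke(main, [
            "simulate", "--family-sizes", "12,14,16", "--panel-size", "10",
            "--chromosomes", "2", "--loci-per-chromosome", "20",
            "--seed", "3", "--out", str(sim_dir),
        ])
        assert result.exit_code == 0, result.output
        for name in ("genotypes.tsv", "kinship.tsv", "families.tsv",
                     "phenotypes.tsv", "h2.tsv", "panel.tsv"):
            assert (sim_dir / name).exists()

        scen_dir = tmp_path / "scen"
        result = runner.invoke(main, [
            "scenario", "--data-dir", str(sim_dir), "--scenario", "S1",
            "--seed", "4", "--out", str(scen_dir),
        ])
        assert result.exit_code == 0, result.output
        report = pd.read_csv(scen_dir / "report.tsv", sep="\t")
        assert len(report) == 6  # 3 families -> 6 ordered pairs

        summary_path = tmp_path / "summary.tsv"
        result = runner.invoke(main, [
            "evaluate", "--report", str(scen_dir / "report.tsv"),
            "--out", str(summary_path),
        ])
        assert result.exit_code == 0, result.output
        assert summary_path.exists()

    def test_optimize_command_writes_design(self, tmp_path):
        from click.testing import CliRunner

        from cdpop.cli import main

        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        runner.invoke(main, [
            "simulate", "--family-sizes", "10,12", "--chromosomes", "2",
            "--loci-per-chromosome", "15", "--seed", "5",
            "--out", str(sim_dir),
        ])
        out_dir = tmp_path / "opt"
        result = runner.invoke(main, [
            "optimize", "--kinship", str(sim_dir / "kinship.tsv"),
            "--families", str(sim_dir / "families.tsv"),
            "--target-family", "F01", "--criterion", "cdpop", "--size", "5",
            "--max-iterations", "60", "--patience", "25", "--restarts", "1",
            "--seed", "6", "--out", str(out_dir),
        ])
        assert result.exit_code == 0, result.output
        design = pd.read_csv(out_dir / "design.tsv", sep="\t")
        assert len(design) == 5
        assert (design.family == "F02").all()
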