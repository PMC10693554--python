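import time

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ch4pred.dataset_io import ConfigurationError
from ch4pred.evaluation import (
    SplitError,
    compute_metrics,
    final_model_choice,
    grouped_split,
    relative_change,
    run_fitting_experiment,
    run_prediction_experiment,
)
from ch4pred.lmm import fit_lmm, information_criteria
from ch4pred.penalized import refit_selected
from ch4pred.dataset_io import prepare_matrix, standardize_train_apply_test
from ch4pred.synthetic import SyntheticConfig, generate


class TestGroupedSplit:
    def test_exact_divisibility(self):
        counts = {f"a{i}": 2 for i in range(10)}
        plan = grouped_split(counts, 0.2, seed=0)
        assert len(plan.test_animals) == 2
        assert sum(counts[a] for a in plan.test_animals) == 4

    def test_sides_are_disjoint_and_exhaustive(self):
        counts = {f"a{i}": 1 + i % 2 for i in range(23)}
        for seed in range(25):
            plan = grouped_split(counts, 0.2, seed=seed)
            assert not set(plan.train_animals) & set(plan.test_animals)
            assert set(plan.train_animals) | set(plan.test_animals) == set(counts)

    def test_deterministic_and_seed_sensitive(self):
        counts = {f"a{i}": 2 for i in range(30)}
        p1, p2 = grouped_split(counts, 0.2, seed=3), grouped_split(counts, 0.2, seed=3)
        assert p1.test_animals == p2.test_animals
        others = [grouped_split(counts, 0.2, seed=s).test_animals for s in range(10)]
        assert len(set(others)) > 1

    def test_share_close_to_target_with_mixed_record_counts(self):
        """Study-shaped counts: test side within one observation of 20%."""
        counts = {f"a{i}": 2 for i in range(101)}
        counts.update({f"s{i}": 1 for i in range(16)})
        target = 0.2 * 218
        for seed in range(50):
            plan = grouped_split(counts, 0.2, seed=seed)
            n_test = sum(counts[a] for a in plan.test_animals)
            assert abs(n_test - target) <= 1.0

    def test_too_few_animals(self):
        with pytest.raises(SplitError):
            grouped_split({"a": 2}, 0.2, seed=0)


class TestComputeMetrics:
    def test_identity_case(self):
        m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m["MSPE"], m["RMSPE"], m["MAE"], m["CCC"]) == (0.0, 0.0, 0.0, 1.0)

    def test_constant_prediction_example(self):
        m = compute_metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert m["MSPE"] == pytest.approx(2 / 3)
        assert m["RMSPE"] == pytest.approx(np.sqrt(2 / 3))
        assert m["MAE"] == pytest.approx(2 / 3)
        assert m["CCC"] == pytest.approx(0.0)  # zero prediction variance

    def test_ccc_with_location_shift(self):
        m = compute_metrics([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        assert m["CCC"] == pytest.approx(4 / 7)

    def test_rmspe_is_root_of_mspe(self):
        rng = np.random.default_rng(0)
        o, p = rng.normal(size=50), rng.normal(size=50)
        m = compute_metrics(o, p)
        assert m["RMSPE"] == pytest.approx(np.sqrt(m["MSPE"]), rel=1e-15)

    def test_length_mismatch_and_empty(self):
        with pytest.raises(ConfigurationError):
            compute_metrics([1.0], [1.0, 2.0])
        with pytest.raises(ConfigurationError):
            compute_metrics([], [])

    @given(st.floats(-50, 50), st.floats(0.1, 20))
    def test_ccc_shift_scale_invariance(self, shift, scale):
        rng = np.random.default_rng(17)
        o = rng.normal(size=40)
        p = 0.6 * o + rng.normal(0, 0.5, 40)
        base = compute_metrics(o, p)["CCC"]
        moved = compute_metrics(scale * o + shift, scale * p + shift)["CCC"]
        assert moved == pytest.approx(base, abs=1e-9)


class TestRelativeChange:
    def test_cases(self):
        assert relative_change(2.0, 2.0) == 0.0
        assert relative_change(1.5, 2.0, "reduction") == pytest.approx(25.0)
        assert relative_change(0.6, 0.5, "increase") == pytest.approx(20.0)

    def test_zero_baseline(self):
        with pytest.raises(ConfigurationError):
            relative_change(1.0, 0.0)


@pytest.fixture(scope="module")
def tiny_run(small_data):
    table, _ = small_data
    return run_prediction_experiment(
        table, "ANIM-B", ["conventional", "glmmLasso"],
        n_replicates=5, base_seed=11,
    )


class TestPredictionExperiment:
    def test_no_animal_straddles_any_split(self, tiny_run, small_data):
        table, _ = small_data
        counts = table.data["animal_id"].value_counts().to_dict()
        for r in sorted(tiny_run.archive["replicate"].unique()):
            plan = grouped_split(counts, 0.2, seed=tiny_run.base_seed + r,
                                 replicate_index=r)
            test_animals = set(
                tiny_run.archive.loc[tiny_run.archive["replicate"] == r, "animal_id"]
            )
            assert test_animals <= set(plan.test_animals)

    def test_pooled_mspe_is_weighted_mean_of_replicates(self, tiny_run):
        sub = tiny_run.archive[tiny_run.archive["method"] == "conventional"]
        per = tiny_run.per_replicate
        per = per[per["method"] == "conventional"]
        weights = sub.groupby("replicate").size()
        weighted = float(
            (per.set_index("replicate")["MSPE"] * weights).sum() / weights.sum()
        )
        assert tiny_run.pooled["conventional"]["MSPE"] == pytest.approx(weighted, rel=1e-12)

    def test_relative_changes_follow_pooled_metrics(self, tiny_run):
        rel = tiny_run.relative["glmmLasso"]
        conv = tiny_run.pooled["conventional"]
        glmm = tiny_run.pooled["glmmLasso"]
        assert rel["RMSPE"] == pytest.approx(100 * (1 - glmm["RMSPE"] / conv["RMSPE"]))
        assert rel["CCC"] == pytest.approx(100 * (glmm["CCC"] / conv["CCC"] - 1))

    def test_deterministic_given_base_seed(self, small_data):
        table, _ = small_data
        kwargs = dict(n_replicates=3, base_seed=5)
        r1 = run_prediction_experiment(table, "ANIM-B", ["conventional"], **kwargs)
        r2 = run_prediction_experiment(table, "ANIM-B", ["conventional"], **kwargs)
        assert r1.pooled == r2.pooled
        assert r1.archive.equals(r2.archive)

    def test_near_noiseless_signal_predicts_almost_perfectly(self):
        """With tiny variances and animal-only effects every route succeeds."""
        cfg = SyntheticConfig(
            n_animals=60, n_single_record_animals=10,
            n_bacteria=20, n_archaea=2, n_protozoa=2, n_fungi=2,
            n_causal_genera=0, sigma_alpha=0.01, sigma=0.01,
            bimodal_offset=0.0, dmi_noise_sd=0.25, seed=13,
        )
        table, _ = generate(cfg)
        rep = run_prediction_experiment(
            table, "ANIM-B",
            ["conventional", "glmmLasso", "LASSO", "SCAD", "RF-B"],
            n_replicates=3, base_seed=0,
            selection_kwargs={"rf_kwargs": {"n_trees": 100, "mtry": 10}},
        )
        for method, metrics in rep.pooled.items():
            assert metrics["RMSPE"] < 0.1, (method, metrics)

    def test_metric_table_layout(self, tiny_run):
        frame = tiny_run.to_frame()
        assert list(frame.columns) == ["conventional", "glmmLasso"]
        assert "RMSPE" in frame.index and "Increase of CCC (%)" in frame.index

    def test_unknown_method_rejected(self, small_data):
        table, _ = small_data
        with pytest.raises(ConfigurationError):
            run_prediction_experiment(table, "ANIM-B", ["nope"], n_replicates=1)

    def test_conventional_protocol_is_fast_at_study_scale(self, study_data):
        table, _ = study_data
        start = time.monotonic()
        run_prediction_experiment(table, "ANIM-B", ["conventional"],
                                  n_replicates=200, base_seed=0)
        assert time.monotonic() - start < 60.0


class TestFittingExperiment:
    def test_conventional_reports_three_predictors(self, study_data):
        table, _ = study_data
        report = run_fitting_experiment(table, "ANIM-B", ["conventional"])
        assert report.n_variables["conventional"] == 3
        coef = report.coefficients["conventional"]
        assert set(coef) == {"(Intercept)", "dmi", "bw", "ap_ratio"}

    def test_bic_minus_aic_identity(self, study_data):
        table, _ = study_data
        report = run_fitting_experiment(table, "ANIM-B", ["conventional", "glmmLasso"])
        for m in report.methods:
            k = report.n_variables[m] + 1 + 2
            assert report.bic[m] - report.aic[m] == pytest.approx(
                k * (np.log(218) - 2), rel=1e-10
            )

    def test_nested_supports_have_monotone_deviance(self, study_matrix):
        fs, _ = study_matrix
        small = refit_selected(fs, ["dmi"], criterion="ML")
        large = refit_selected(fs, ["dmi", "bw"], criterion="ML")
        assert large.loglik_ml >= small.loglik_ml - 1e-8

    def test_reductions_vs_conventional(self, study_data):
        table, _ = study_data
        report = run_fitting_experiment(table, "ANIM-B", ["conventional", "glmmLasso"])
        assert report.reductions["glmmLasso"]["BIC"] == pytest.approx(
            report.bic["conventional"] - report.bic["glmmLasso"]
        )


class TestFinalModelChoice:
    def _reports(self):
        class M:  # minimal stand-ins with the fields final_model_choice reads
            pass

        metric = M()
        metric.methods = ("conventional", "glmmLasso", "SCAD")
        metric.pooled = {
            "conventional": {"RMSPE": 3.0},
            "glmmLasso": {"RMSPE": 2.8},
            "SCAD": {"RMSPE": 2.85},
        }
        fit = M()
        fit.methods = metric.methods
        fit.bic = {"conventional": 1070.0, "glmmLasso": 1051.0, "SCAD": 1065.0}
        return metric, fit

    def test_dominant_method_is_flagged(self):
        metric, fit = self._reports()
        choice = final_model_choice(metric, fit, rmspe_tolerance=0.05)
        assert choice["flagged"] == "glmmLasso"
        assert choice["prediction_ranking"][0] == "glmmLasso"
        assert choice["fitting_ranking"][0] == "glmmLasso"

    def test_tolerance_window_admits_near_best(self):
        metric, fit = self._reports()
        fit.bic["SCAD"] = 1000.0  # SCAD best in BIC, within 5% RMSPE of best
        choice = final_model_choice(metric, fit, rmspe_tolerance=0.05)
        assert choice["flagged"] == "SCAD"
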