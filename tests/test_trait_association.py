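"""Trait models, cross-validation protocols, importance and mediation."""

import numpy as np
import pandas as pd
import pytest

from senosig import synthetic_data as syn
from senosig.burden_scoring import ElasticNetConfig
from senosig.trait_association import (
    compare_paired_metrics,
    cross_study_transfer,
    cross_validate,
    fit_trait_model,
    mediate,
    nested_cross_validate,
    relative_importance,
)


def _cohort(seed, n=400, slope=2.0, noise=0.05):
    rng = np.random.default_rng(seed)
    score = rng.normal(size=n)
    df = pd.DataFrame(
        {
            "score": score,
            "age": rng.uniform(30, 90, n),
            "sex": rng.integers(0, 2, n),
            "trait": slope * score + rng.normal(0, noise, n),
        }
    )
    return df


class TestFitTraitModel:
    def test_effect_recovered_in_noiseless_limit(self):
        df = _cohort(0, noise=1e-6)
        res = fit_trait_model(df, "trait", "score", covariates=("age", "sex"))
        assert res.effect == pytest.approx(2.0, abs=1e-3)
        assert res.family == "gaussian"

    def test_null_type_one_error(self):
        hits = 0
        for s in range(200):
            rng = np.random.default_rng(s)
            df = pd.DataFrame(
                {
                    "score": rng.normal(size=120),
                    "age": rng.uniform(30, 90, 120),
                    "trait": rng.normal(size=120),
                }
            )
            res = fit_trait_model(df, "trait", "score", covariates=("age",))
            hits += res.p_value < 0.05
        assert 2 <= hits <= 22  # ~5% of 200, binomial tolerance

    def test_noise_covariate_leaves_effect_unbiased(self):
        df = _cohort(1, noise=0.5)
        a = fit_trait_model(df, "trait", "score", covariates=("age",))
        b = fit_trait_model(df, "trait", "score", covariates=("age", "sex"))
        assert a.effect == pytest.approx(b.effect, abs=0.02)

    def test_logistic_family_and_constant_predictor(self):
        rng = np.random.default_rng(2)
        df = _cohort(2)
        df["disease"] = (rng.uniform(size=len(df)) < 0.3).astype(int)
        res = fit_trait_model(df, "disease", "score", covariates=("age",))
        assert res.family == "binomial"
        df["flat"] = 1.0
        with pytest.raises(ValueError):
            fit_trait_model(df, "trait", "flat", covariates=("age",))


class TestCrossValidate:
    def test_noiseless_r2(self):
        df = _cohort(3, noise=1e-8)
        cv = cross_validate(df, "trait", df["score"], seed=0)
        assert cv.mean_r2 >= 0.99
        assert cv.n_iterations == 10

    def test_null_r2_near_zero(self):
        rng = np.random.default_rng(999)
        df = _cohort(4, n=1000)
        df["trait"] = rng.normal(size=1000)
        cv = cross_validate(df, "trait", df["score"], seed=1)
        assert abs(cv.mean_r2) < 0.05

    def test_seeded_reproducibility(self):
        df = _cohort(5)
        a = cross_validate(df, "trait", df["score"], seed=7)
        b = cross_validate(df, "trait", df["score"], seed=7)
        pd.testing.assert_frame_equal(a.metrics, b.metrics)

    def test_binary_metrics_present(self):
        rng = np.random.default_rng(6)
        df = _cohort(6)
        df["disease"] = (
            rng.uniform(size=len(df)) < 1 / (1 + np.exp(-df["score"]))
        ).astype(int)
        cv = cross_validate(df, "disease", df["score"], seed=0)
        assert {"r2", "auc"} <= set(cv.metrics.columns)
        assert cv.metrics["auc"].mean() > 0.6


class TestNestedAndTransfer:
    @pytest.fixture(scope="class")
    def planted(self):
        cat, truth = syn.simulate_catalog(syn.CatalogSimConfig(seed=21))
        cohort, truth = syn.simulate_cohort(
            syn.CohortSimConfig(n_participants=500, burden_loading=0.5, seed=22),
            truth,
        )
        return cohort, truth

    def test_nested_reports_fold_panels(self, planted):
        cohort, truth = planted
        cfg = ElasticNetConfig(covariates=("age", "sex", "race"), seed=0, n_cv_folds=5)
        res = nested_cross_validate(
            cohort, "frailty", truth.planted_panel, "negative-health", cfg,
            n_iter=3, seed=0,
        )
        assert len(res.panels) == 3
        assert res.metrics.shape[0] == 3

    def test_transfer_features_are_intersection(self, planted):
        cohort_a, truth = planted
        cohort_b, _ = syn.simulate_cohort(
            syn.CohortSimConfig(n_participants=500, burden_loading=0.5, seed=23),
            truth,
        )
        cfg = ElasticNetConfig(covariates=("age", "sex", "race"), seed=0, n_cv_folds=5)
        out = cross_study_transfer(
            cohort_a, cohort_b, "frailty", truth.planted_panel, "negative-health", cfg
        )
        assert out["trainable"]
        assert "A_to_B" in out and "B_to_A" in out
        # exchangeable cohorts: transfer works in both directions
        assert out["A_to_B"]["r2"] > 0.02 and out["B_to_A"]["r2"] > 0.02


class TestComparePairedMetrics:
    def test_identical_vectors(self):
        out = compare_paired_metrics([1, 2, 3], [1, 2, 3])
        assert out["mean_difference"] == 0.0
        assert out["verdict"] == "no difference"

    def test_constant_shift(self):
        out = compare_paired_metrics([1.0, 2.0, 3.0], [1.1, 2.1, 3.1])
        assert out["mean_difference"] == pytest.approx(0.1)
        assert out["test"] == "zero-variance"

    def test_power_of_paired_t(self):
        wins = 0
        for s in range(200):
            rng = np.random.default_rng(s)
            a = rng.normal(0.5, 0.01, 10)
            b = rng.normal(0.4, 0.01, 10)
            out = compare_paired_metrics(a, b)
            if out.get("p_value", 1.0) < 0.01:
                wins += 1
        assert wins >= 190

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compare_paired_metrics([1, 2], [1, 2, 3])


class TestRelativeImportance:
    def test_orthogonal_closed_form(self):
        rng = np.random.default_rng(7)
        n = 100_000
        A = rng.normal(size=n)
        B = rng.normal(size=n)
        y = 0.6 * A + np.sqrt(1 - 0.36) * rng.normal(size=n)
        df = pd.DataFrame({"y": y, "A": A, "B": B})
        out = relative_importance(df, "y", "A", "B", covariates=(), n_boot=100, seed=0)
        assert out["importance_a"] == pytest.approx(0.36, abs=0.01)
        assert out["importance_b"] == pytest.approx(0.0, abs=0.01)

    def test_importances_sum_to_joint_increment(self):
        rng = np.random.default_rng(8)
        n = 2000
        A = rng.normal(size=n)
        B = 0.5 * A + rng.normal(size=n)
        y = 0.4 * A + 0.3 * B + rng.normal(size=n)
        df = pd.DataFrame({"y": y, "A": A, "B": B, "c": rng.normal(size=n)})
        out = relative_importance(df, "y", "A", "B", covariates=("c",), n_boot=100, seed=0)

        def r2(cols):
            X = df[cols].to_numpy()
            X = np.column_stack([np.ones(n), X])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            return 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))

        joint = r2(["c", "A", "B"]) - r2(["c"])
        assert out["importance_a"] + out["importance_b"] == pytest.approx(joint, abs=1e-10)

    def test_collinear_scores_rejected(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=50)
        df = pd.DataFrame({"y": rng.normal(size=50), "A": A, "B": 2 * A})
        with pytest.raises(ValueError):
            relative_importance(df, "y", "A", "B", covariates=(), n_boot=100)


class TestMediate:
    def test_linear_decomposition_exact(self):
        d = syn.simulate_mediation_data(800, 0.5, 0.8, 0.4, seed=1)
        res = mediate(d, "exposure", "mediator", "outcome", n_boot=100, seed=0)
        assert res.total == pytest.approx(res.acme + res.ade, abs=1e-10)

    def test_no_indirect_path(self):
        d = syn.simulate_mediation_data(3000, 0.0, 0.8, 0.4, seed=2)
        res = mediate(d, "exposure", "mediator", "outcome", n_boot=200, seed=0)
        lo, hi = res.ci["acme"]
        assert lo <= 0.0 <= hi
        assert abs(res.acme) < 0.05

    def test_full_mediation_limit(self):
        d = syn.simulate_mediation_data(
            5000, 0.5, 0.8, 0.0, mediator_noise_sd=0.05, outcome_noise_sd=0.05, seed=3
        )
        res = mediate(d, "exposure", "mediator", "outcome", n_boot=100, seed=0)
        assert res.prop_mediated == pytest.approx(1.0, abs=0.05)

    def test_binary_outcome_runs(self):
        d = syn.simulate_mediation_data(800, 0.8, 1.0, 0.3, family="binomial", seed=4)
        res = mediate(d, "exposure", "mediator", "outcome", n_boot=100, seed=0, n_sim=50)
        assert res.acme > 0
        assert res.ci["acme"][0] <= res.acme <= res.ci["acme"][1]

    def test_guard_rails(self):
        d = syn.simulate_mediation_data(200, 0.5, 0.8, 0.4, seed=5)
        with pytest.raises(ValueError):
            mediate(d, "exposure", "mediator", "outcome", n_boot=50)
        d["mediator"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            mediate(d, "exposure", "mediator", "outcome", n_boot=100)
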