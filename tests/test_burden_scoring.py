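"""Panel selection, truncation, composite scores and the High-Impact Panel."""

import numpy as np
import pandas as pd
import pytest

from senosig.burden_scoring import (
    ElasticNetConfig,
    PanelSpec,
    composite_score,
    high_impact_panel,
    infer_family,
    panel_zscore_stats,
    rank_and_truncate,
    select_features,
)


def _signal_cohort(seed, n=500, p=200, k=10, effect=0.3, binary=False):
    rng = np.random.default_rng(seed)
    cols = [f"P{i:04d}" for i in range(p)]
    X = rng.normal(size=(n, p))
    eta = X[:, :k] @ np.full(k, effect)
    df = pd.DataFrame(X, columns=cols)
    df["age"] = rng.uniform(20, 90, n)
    df["sex"] = rng.integers(0, 2, n)
    if binary:
        df["trait"] = (rng.uniform(size=n) < 1 / (1 + np.exp(-(eta - 0.2)))).astype(int)
    else:
        df["trait"] = eta + 0.02 * df["age"] + rng.normal(size=n)
    return df, cols


class TestSelectFeatures:
    def test_planted_recovery(self):
        recalls = []
        for s in range(5):
            df, cols = _signal_cohort(s)
            cfg = ElasticNetConfig(covariates=("age", "sex"), seed=s)
            sel = select_features(df, "trait", cols, cfg)
            recalls.append(len(set(sel["protein"]) & set(cols[:10])) / 10)
        assert np.mean(recalls) >= 0.8

    def test_null_pool_nearly_empty(self):
        counts = []
        for s in range(5):
            rng = np.random.default_rng(100 + s)
            df, cols = _signal_cohort(s, n=300)
            df["trait"] = rng.normal(size=len(df))
            cfg = ElasticNetConfig(covariates=("age", "sex"), seed=s)
            counts.append(len(select_features(df, "trait", cols, cfg)))
        assert np.mean(counts) <= 2

    def test_duplicated_feature_grouping(self):
        # the ridge component spreads weight over exact copies
        df, cols = _signal_cohort(3, n=400, p=50, k=3, effect=0.6)
        df["DUP"] = df[cols[0]]
        cfg = ElasticNetConfig(covariates=("age",), seed=0, lambda_rule="min")
        sel = select_features(df, "trait", cols + ["DUP"], cfg)
        chosen = set(sel["protein"])
        assert {cols[0], "DUP"} <= chosen

    def test_determinism(self):
        df, cols = _signal_cohort(4)
        cfg = ElasticNetConfig(covariates=("age", "sex"), seed=9)
        a = select_features(df, "trait", cols, cfg)
        b = select_features(df, "trait", cols, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_binomial_family(self):
        df, cols = _signal_cohort(5, n=400, p=40, k=5, effect=0.8, binary=True)
        cfg = ElasticNetConfig(
            covariates=("age", "sex"), seed=0, n_cv_folds=3, n_lambdas=12
        )
        sel = select_features(df, "trait", cols, cfg)
        assert len(set(sel["protein"]) & set(cols[:5])) >= 3

    def test_constant_trait_rejected(self):
        df, cols = _signal_cohort(6, n=50, p=10)
        df["trait"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            select_features(df, "trait", cols, ElasticNetConfig(covariates=("age",)))


class TestRankAndTruncate:
    def _selected(self, effects):
        return pd.DataFrame(
            {"protein": [f"P{i:03d}" for i in range(len(effects))], "effect": effects}
        )

    def test_top_25_by_effect(self):
        effects = np.linspace(3.0, 0.1, 30)
        panel = rank_and_truncate(self._selected(effects), "frailty", "negative-health")
        assert len(panel) == 25
        assert panel.proteins[0] == "P000"
        kept = np.sort(np.abs(list(panel.effects.values())))[::-1]
        assert kept[-1] >= 0.1 and len(kept) == 25

    def test_sign_filter(self):
        sel = self._selected([1.0, -2.0, 0.5])
        neg = rank_and_truncate(sel, "frailty", "negative-health")
        assert set(neg.proteins) == {"P000", "P002"}
        pos = rank_and_truncate(sel, "grip", "positive-health")
        assert set(pos.proteins) == {"P001"}
        both = rank_and_truncate(sel, "age", "any")
        assert len(both) == 3

    def test_small_and_empty_panels(self):
        assert len(rank_and_truncate(self._selected([1.0, 2.0, 3.0]), "t", "any")) == 3
        assert len(rank_and_truncate(self._selected([]), "t", "any")) == 0

    def test_tie_break_lexicographic(self):
        sel = pd.DataFrame({"protein": ["PB", "PA", "PC"], "effect": [1.0, 1.0, 1.0]})
        panel = rank_and_truncate(sel, "t", "negative-health", k=2)
        assert panel.proteins == ["PA", "PB"]

    def test_row_permutation_invariance(self):
        sel = self._selected(np.linspace(2.0, 0.2, 12))
        shuffled = sel.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = rank_and_truncate(sel, "t", "any", k=5)
        b = rank_and_truncate(shuffled, "t", "any", k=5)
        assert a.proteins == b.proteins


class TestCompositeScore:
    def test_two_point_zscore(self):
        cohort = pd.DataFrame({"PX": [1.0, 3.0]})
        s = composite_score(cohort, ["PX"])
        assert s.tolist() == pytest.approx([-np.sqrt(0.5), np.sqrt(0.5)], abs=1e-6)

    def test_single_protein_identity(self, rng):
        cohort = pd.DataFrame({"PX": rng.normal(size=30)})
        s = composite_score(cohort, ["PX"])
        z = (cohort["PX"] - cohort["PX"].mean()) / cohort["PX"].std(ddof=1)
        assert np.allclose(s, z)

    def test_mean_zero_and_affine_invariance(self, rng):
        cohort = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        s = composite_score(cohort, list("abcd"))
        assert abs(s.mean()) < 1e-12
        rescaled = cohort.copy()
        rescaled["a"] = 100.0 * rescaled["a"] - 7.0
        s2 = composite_score(rescaled, list("abcd"))
        assert np.allclose(s, s2)

    def test_zero_variance_handling(self, rng):
        cohort = pd.DataFrame({"a": rng.normal(size=20), "b": 5.0})
        s = composite_score(cohort, ["a", "b"])
        assert np.allclose(s, composite_score(cohort, ["a"]))
        with pytest.raises(ValueError):
            composite_score(cohort, ["b"])
        with pytest.raises(ValueError):
            composite_score(cohort, [])

    def test_out_of_sample_stats(self, rng):
        cohort = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        stats = panel_zscore_stats(cohort.iloc[:30], ["a", "b"])
        s = composite_score(cohort.iloc[30:], ["a", "b"], stats=stats)
        assert len(s) == 20 and abs(s.mean()) > 0  # not forced to zero out of sample


class TestHighImpactPanel:
    def _panels(self, membership):
        return {
            t: PanelSpec(t, "any", proteins=list(members))
            for t, members in membership.items()
        }

    def test_at_least_half_threshold(self):
        members = {f"t{i}": ["HIT"] if i < 5 else ["other"] for i in range(10)}
        hip = high_impact_panel(self._panels(members))
        assert "HIT" in hip  # 5 of 10 traits
        members = {f"t{i}": ["HIT"] if i < 4 else ["other"] for i in range(10)}
        assert "HIT" not in high_impact_panel(self._panels(members))

    def test_two_trait_list(self):
        hip = high_impact_panel(self._panels({"t1": ["A"], "t2": ["B"]}))
        assert hip == {"A", "B"}

    def test_needs_two_traits(self):
        with pytest.raises(ValueError):
            high_impact_panel(self._panels({"t1": ["A"]}))
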