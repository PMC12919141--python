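"""Covariate-adjusted trait models on burden scores, and their comparison.

Implements the cohort-side statistical toolkit: linear/logistic trait
models of the form ``trait ~ predictor + age + sex + race``; repeated
90/10 cross-validation of single-panel composite scores; nested
cross-validation where feature selection is redone inside each training
split; cross-study transfer on the intersection of per-study selections;
paired comparison of iteration-matched metrics with a Shapiro-Wilk
normality gate; LMG relative-importance decomposition of two competing
scores; and potential-outcomes mediation (ACME / ADE / proportion
mediated) with nonparametric bootstrap confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .burden_scoring import (
    ElasticNetConfig,
    PanelSpec,
    build_covariate_design,
    composite_score,
    infer_family,
    panel_zscore_stats,
    rank_and_truncate,
    select_features,
)

__all__ = [
    "TraitModelResult",
    "CVResult",
    "MediationResult",
    "fit_trait_model",
    "cross_validate",
    "nested_cross_validate",
    "cross_study_transfer",
    "compare_paired_metrics",
    "relative_importance",
    "mediate",
]

logger = logging.getLogger(__name__)


@dataclass
class TraitModelResult:
    trait: str
    predictor: str
    effect: float
    se: float
    p_value: float
    family: str
    covariates: tuple[str, ...]
    n: int
    separation_flag: bool = False

    def summary(self) -> str:
        return (
            f"{self.trait} ~ {self.predictor} [{self.family}, n={self.n}]: "
            f"effect={self.effect:+.4f} (se {self.se:.4f}, p {self.p_value:.3g})"
            + (" [separation]" if self.separation_flag else "")
        )


@dataclass
class CVResult:
    """Per-iteration held-out metrics of a repeated train/test protocol."""

    trait: str
    family: str
    metrics: pd.DataFrame  # columns: iteration, r2 [, auc]
    train_frac: float
    seed: int
    panels: list[PanelSpec] | None = None

    @property
    def n_iterations(self) -> int:
        return len(self.metrics)

    @property
    def mean_r2(self) -> float:
        return float(self.metrics["r2"].mean())


@dataclass
class MediationResult:
    acme: float
    ade: float
    total: float
    prop_mediated: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_boot: int = 0

    def summary(self) -> str:
        lines = [
            f"ACME             {self.acme:+.4f}  CI {self.ci.get('acme')}",
            f"ADE              {self.ade:+.4f}  CI {self.ci.get('ade')}",
            f"Total effect     {self.total:+.4f}  CI {self.ci.get('total')}",
            f"Prop. mediated   {self.prop_mediated:+.4f}  CI {self.ci.get('prop_mediated')}",
        ]
        return "\n".join(lines)


def _as_series(cohort: pd.DataFrame, predictor) -> pd.Series:
    if isinstance(predictor, str):
        return cohort[predictor].rename(predictor)
    s = pd.Series(predictor)
    if s.name is None:
        s = s.rename("score")
    return s.reindex(cohort.index)


def fit_trait_model(
    cohort: pd.DataFrame,
    trait: str,
    predictor,
    covariates: Sequence[str] = ("age", "sex", "race"),
) -> TraitModelResult:
    """OLS (continuous) or logistic (binary) trait model, covariate adjusted.

    ``predictor`` is a cohort column name or a participant-indexed Series
    (e.g. a composite score). Perfect separation in the logistic case is
    flagged on the result rather than silently accepted.
    """
    y = cohort[trait].astype(float)
    x = _as_series(cohort, predictor).astype(float)
    if x.std(ddof=0) < 1e-12:
        raise ValueError("predictor is constant")
    family = infer_family(y.rename(trait))
    C = build_covariate_design(cohort, covariates)
    for col in C.columns[1:]:
        if C[col].std(ddof=0) < 1e-12:
            raise ValueError(f"covariate {col!r} is constant")
    D = pd.concat([x.to_frame("_predictor_"), C], axis=1).astype(float)
    separation = False
    if family == "gaussian":
        res = sm.OLS(y, D).fit()
    else:
        try:
            with np.errstate(all="ignore"):
                res = sm.Logit(y, D).fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", True) or np.abs(
                res.params["_predictor_"]
            ) > 1e3:
                separation = True
        except Exception:  # statsmodels raises on perfect separation
            separation = True
            res = sm.Logit(y, D).fit_regularized(alpha=1e-6, disp=0)
    eff = float(res.params["_predictor_"])
    se = float(res.bse["_predictor_"]) if hasattr(res, "bse") else float("nan")
    p = float(res.pvalues["_predictor_"]) if hasattr(res, "pvalues") else float("nan")
    return TraitModelResult(
        trait=trait,
        predictor=str(x.name),
        effect=eff,
        se=se,
        p_value=p,
        family=family,
        covariates=tuple(covariates),
        n=len(y),
        separation_flag=separation,
    )


def _split_metrics(
    y_train: np.ndarray,
    x_train: np.ndarray,
    y_test: np.ndarray,
    x_test: np.ndarray,
    family: str,
) -> dict[str, float]:
    Dtr = sm.add_constant(x_train)
    Dte = sm.add_constant(x_test, has_constant="add")
    if family == "gaussian":
        fit = sm.OLS(y_train, Dtr).fit()
        pred = Dte @ fit.params
        r = np.corrcoef(pred, y_test)[0, 1]
        return {"r2": float(r**2) if np.isfinite(r) else 0.0}
    fit = sm.Logit(y_train, Dtr).fit(disp=0, maxiter=200)
    prob = 1.0 / (1.0 + np.exp(-(Dte @ fit.params)))
    r = np.corrcoef(prob, y_test)[0, 1]
    return {
        "r2": float(r**2) if np.isfinite(r) else 0.0,
        "auc": float(roc_auc_score(y_test, prob)),
    }


def _draw_split(
    rng: np.random.Generator, n: int, train_frac: float, y: np.ndarray, family: str
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test split; binary outcomes redraw degenerate folds."""
    for attempt in range(100):
        perm = rng.permutation(n)
        n_train = int(round(train_frac * n))
        tr, te = perm[:n_train], perm[n_train:]
        if family == "gaussian":
            return tr, te
        if len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2:
            if attempt:
                logger.info("redrew %d degenerate folds", attempt)
            return tr, te
    raise RuntimeError("could not draw a split with both outcome classes")


def cross_validate(
    cohort: pd.DataFrame,
    trait: str,
    scores: pd.Series,
    n_iter: int = 10,
    train_frac: float = 0.9,
    seed: int = 0,
) -> CVResult:
    """Repeated random 90/10 validation of a single precomputed score.

    Each iteration draws an independent split, trains ``trait ~ score``
    on the training fraction and reports test-set R-squared (squared
    Pearson correlation of prediction and truth); binary traits also get
    the AUC of the predicted probability.
    """
    y = cohort[trait].astype(float).to_numpy()
    x = _as_series(cohort, scores).astype(float).to_numpy()
    family = infer_family(cohort[trait])
    rng = np.random.default_rng(seed)
    rows = []
    for it in range(n_iter):
        tr, te = _draw_split(rng, len(y), train_frac, y, family)
        m = _split_metrics(y[tr], x[tr], y[te], x[te], family)
        rows.append({"iteration": it, **m})
    return CVResult(trait, family, pd.DataFrame(rows), train_frac, seed)


def nested_cross_validate(
    cohort: pd.DataFrame,
    trait: str,
    candidate_pool: Iterable[str],
    polarity: str = "any",
    config: ElasticNetConfig | None = None,
    n_iter: int = 10,
    train_frac: float = 0.9,
    seed: int = 0,
    k: int = 25,
) -> CVResult:
    """Leakage-free repeated validation: selection redone per training split.

    Per iteration the elastic-net selection, sign filter, truncation and
    z-scoring statistics are all computed on the training 90% only; the
    held-out 10% is scored with training statistics. Fold panels may
    differ across iterations and are returned alongside the metrics.
    """
    config = config or ElasticNetConfig()
    pool = sorted(candidate_pool)
    y = cohort[trait].astype(float).to_numpy()
    family = infer_family(cohort[trait])
    rng = np.random.default_rng(seed)
    rows, panels = [], []
    for it in range(n_iter):
        tr, te = _draw_split(rng, len(y), train_frac, y, family)
        train, test = cohort.iloc[tr], cohort.iloc[te]
        sel = select_features(train, trait, pool, config)
        panel = rank_and_truncate(sel, trait, polarity, k=k)
        panels.append(panel)
        if len(panel) == 0:
            logger.warning("iteration %d selected an empty panel", it)
            rows.append({"iteration": it, "r2": 0.0})
            continue
        zstats = panel_zscore_stats(train, panel.proteins)
        s_tr = composite_score(train, panel, stats=zstats).to_numpy()
        s_te = composite_score(test, panel, stats=zstats).to_numpy()
        m = _split_metrics(y[tr], s_tr, y[te], s_te, family)
        rows.append({"iteration": it, **m})
    return CVResult(
        trait, family, pd.DataFrame(rows), train_frac, seed, panels=panels
    )


def cross_study_transfer(
    cohort_a: pd.DataFrame,
    cohort_b: pd.DataFrame,
    trait: str,
    candidate_pool: Iterable[str],
    polarity: str = "any",
    config: ElasticNetConfig | None = None,
    k: int = 25,
) -> dict:
    """Train on one study, evaluate on the other, both directions.

    Features are the intersection of each study's sign-filtered elastic-net
    selections, truncated to ``k`` by mean absolute effect across studies;
    scores are z-scored within each study; the trait model is fit wholly on
    the training study. An empty intersection is reported as untrainable.
    """
    config = config or ElasticNetConfig()
    pool = sorted(set(candidate_pool) & set(cohort_a.columns) & set(cohort_b.columns))
    family = infer_family(cohort_a[trait])
    panels = {}
    for name, cohort in (("A", cohort_a), ("B", cohort_b)):
        sel = select_features(cohort, trait, pool, config)
        panels[name] = rank_and_truncate(sel, trait, polarity, k=len(pool))
    shared = sorted(set(panels["A"].proteins) & set(panels["B"].proteins))
    out = {"features": shared, "trainable": bool(shared)}
    if not shared:
        logger.warning("empty cross-study feature intersection for %s", trait)
        return out
    mean_abs = {
        p: 0.5 * (abs(panels["A"].effects[p]) + abs(panels["B"].effects[p]))
        for p in shared
    }
    top = sorted(shared, key=lambda p: (-mean_abs[p], p))[:k]
    out["features"] = top
    for src, dst, tag in (
        (cohort_a, cohort_b, "A_to_B"),
        (cohort_b, cohort_a, "B_to_A"),
    ):
        s_src = composite_score(src, top).to_numpy()
        s_dst = composite_score(dst, top).to_numpy()
        out[tag] = _split_metrics(
            src[trait].to_numpy(float), s_src, dst[trait].to_numpy(float), s_dst, family
        )
    return out


def compare_paired_metrics(
    metrics_a: Sequence[float], metrics_b: Sequence[float]
) -> dict:
    """Paired comparison of iteration-matched metric vectors.

    Differences are first screened with a Shapiro-Wilk normality test; if
    p > 0.05 a paired t-test is used, otherwise a Wilcoxon signed-rank test
    with a flag. Identical or constant-difference inputs take an explicit
    zero-variance path instead of crashing.
    """
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired metric vectors must have equal length")
    d = b - a
    out: dict = {"mean_difference": float(d.mean())}
    if np.allclose(d, d[0]):
        out.update(
            test="zero-variance",
            shapiro_p=float("nan"),
            p_value=float("nan"),
            verdict="no difference" if abs(d[0]) < 1e-12 else "constant shift",
        )
        return out
    shapiro_p = float(sps.shapiro(d).pvalue)
    out["shapiro_p"] = shapiro_p
    if shapiro_p > 0.05:
        out["test"] = "paired-t"
        out["p_value"] = float(sps.ttest_rel(b, a).pvalue)
    else:
        out["test"] = "wilcoxon"
        out["p_value"] = float(sps.wilcoxon(b, a).pvalue)
        out["nonnormal_flag"] = True
    return out


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    D = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    tss = ((y - y.mean()) ** 2).sum()
    return float(1.0 - (resid**2).sum() / tss) if tss > 0 else 0.0


def _lmg_pair(
    y: np.ndarray, A: np.ndarray, B: np.ndarray, C: np.ndarray
) -> tuple[float, float]:
    base = _r2(y, C)
    rA = _r2(y, np.column_stack([C, A]) if C.size else A[:, None])
    rB = _r2(y, np.column_stack([C, B]) if C.size else B[:, None])
    rAB = _r2(y, np.column_stack([C, A, B]) if C.size else np.column_stack([A, B]))
    imp_a = 0.5 * (rA - base) + 0.5 * (rAB - rB)
    imp_b = 0.5 * (rB - base) + 0.5 * (rAB - rA)
    return imp_a, imp_b


def relative_importance(
    cohort: pd.DataFrame,
    trait: str,
    score_a,
    score_b,
    covariates: Sequence[str] = ("age", "sex", "race"),
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """LMG decomposition of trait variance between two competing scores.

    Each score's importance is its R-squared increment averaged over the
    two orders of entry, with the covariates always in the base model; the
    two importances sum to the joint increment of adding both scores.
    Percentile bootstrap 95% CIs over participants.
    """
    y = cohort[trait].astype(float).to_numpy()
    A = _as_series(cohort, score_a).astype(float).to_numpy()
    B = _as_series(cohort, score_b).astype(float).to_numpy()
    r = np.corrcoef(A, B)[0, 1]
    if abs(r) > 1 - 1e-10:
        raise ValueError("scores are collinear; importance is not identified")
    C = build_covariate_design(cohort, covariates).to_numpy(float)[:, 1:]
    imp_a, imp_b = _lmg_pair(y, A, B, C)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 2))
    n = len(y)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[i] = _lmg_pair(y[idx], A[idx], B[idx], C[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    return {
        "importance_a": imp_a,
        "importance_b": imp_b,
        "ci_a": (float(lo[0]), float(hi[0])),
        "ci_b": (float(lo[1]), float(hi[1])),
        "n_boot": n_boot,
    }


def _mediation_point(
    exposure: np.ndarray,
    mediator: np.ndarray,
    outcome: np.ndarray,
    C: np.ndarray,
    family: str,
    rng: np.random.Generator,
    n_sim: int = 100,
) -> tuple[float, float, float]:
    """Plug-in potential-outcomes ACME / ADE / total for one dataset."""
    n = len(outcome)
    Dm = np.column_stack([np.ones(n), exposure, C]) if C.size else np.column_stack(
        [np.ones(n), exposure]
    )
    beta_m, *_ = np.linalg.lstsq(Dm, mediator, rcond=None)
    resid = mediator - Dm @ beta_m
    sigma_m = float(np.sqrt((resid**2).sum() / max(n - Dm.shape[1], 1)))

    Do = (
        np.column_stack([np.ones(n), mediator, exposure, C])
        if C.size
        else np.column_stack([np.ones(n), mediator, exposure])
    )
    if family == "gaussian":
        beta_o, *_ = np.linalg.lstsq(Do, outcome, rcond=None)
        a_hat = beta_m[1]
        b_hat = beta_o[1]
        c_hat = beta_o[2]
        acme = float(a_hat * b_hat)
        ade = float(c_hat)
        return acme, ade, acme + ade

    logit = sm.Logit(outcome, Do).fit(disp=0, maxiter=200)
    beta_o = np.asarray(logit.params)

    def m_pred(t: float) -> np.ndarray:
        D = Dm.copy()
        D[:, 1] = t
        return D @ beta_m

    # linear predictor with the mediator and exposure terms zeroed out;
    # counterfactual draws are added back in, vectorized over draws
    base = Do.copy()
    base[:, 1] = 0.0
    base[:, 2] = 0.0
    eta_base = base @ beta_o

    def y_prob(t: float, m_draw: np.ndarray) -> np.ndarray:
        eta = eta_base[None, :] + beta_o[1] * m_draw + beta_o[2] * t
        return 1.0 / (1.0 + np.exp(-eta))

    eps = rng.normal(0.0, sigma_m, size=(n_sim, n))
    m1 = m_pred(1.0)[None, :] + eps
    m0 = m_pred(0.0)[None, :] + eps
    acmes, ades = [], []
    for t in (0.0, 1.0):
        acmes.append(np.mean(y_prob(t, m1) - y_prob(t, m0)))
    for t in (0.0, 1.0):
        mt = m1 if t == 1.0 else m0
        ades.append(np.mean(y_prob(1.0, mt) - y_prob(0.0, mt)))
    acme = float(np.mean(acmes))
    ade = float(np.mean(ades))
    return acme, ade, acme + ade


def mediate(
    data: pd.DataFrame,
    exposure: str,
    mediator,
    outcome: str,
    covariates: Sequence[str] = (),
    n_boot: int = 1000,
    seed: int = 0,
    n_sim: int = 100,
) -> MediationResult:
    """Potential-outcomes mediation with nonparametric bootstrap CIs.

    The mediator model is linear; the outcome model is linear or logistic
    depending on the outcome. In the linear-linear case the average causal
    mediation effect (ACME) is the product of coefficients a*b, the average
    direct effect (ADE) is c', and total = ACME + ADE exactly. Binary
    outcomes use counterfactual simulation of the mediator on the
    probability scale, averaged over both exposure arms. Percentile 95%
    CIs come from ``n_boot`` resamples of participants (minimum 100).
    """
    if n_boot < 100:
        raise ValueError("n_boot below 100 is rejected by default")
    x = data[exposure].astype(float).to_numpy()
    m = _as_series(data, mediator).astype(float).to_numpy()
    y = data[outcome].astype(float).to_numpy()
    if np.std(m) < 1e-12:
        raise ValueError("mediator is constant")
    family = infer_family(data[outcome])
    C = (
        build_covariate_design(data, covariates).to_numpy(float)[:, 1:]
        if covariates
        else np.empty((len(y), 0))
    )
    rng = np.random.default_rng(seed)
    acme, ade, total = _mediation_point(x, m, y, C, family, rng, n_sim)
    pm = acme / total if abs(total) > 1e-12 else float("nan")

    n = len(y)
    draws = np.empty((n_boot, 4))
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            a_i, d_i, t_i = _mediation_point(
                x[idx], m[idx], y[idx], C[idx], family, rng, n_sim
            )
        except Exception:
            a_i = d_i = t_i = np.nan
        p_i = a_i / t_i if abs(t_i) > 1e-12 else np.nan
        draws[i] = (a_i, d_i, t_i, p_i)
    lo, hi = np.nanpercentile(draws, [2.5, 97.5], axis=0)
    ci = {
        name: (float(lo[j]), float(hi[j]))
        for j, name in enumerate(["acme", "ade", "total", "prop_mediated"])
    }
    return MediationResult(acme, ade, total, pm, ci, n_boot)
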