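"""Trait-specific protein panels and composite senescence-burden scores.

The scoring protocol: elastic-net (mixing 0.5 between lasso and ridge)
feature selection from a candidate protein pool, with age/sex/race-style
covariates kept in the model but *unpenalized*; the selected proteins are
sign-filtered by trait polarity (only positively associated proteins for
negative-health traits such as frailty, only inversely associated proteins
for positive-health traits such as grip strength), ordered by absolute
standardized effect and truncated to at most 25; the panel is condensed
into a composite burden score as the per-participant mean of z-scored
abundances. Proteins selected for at least half of a trait list form the
High-Impact Panel (HIP).

Gaussian traits use the Frisch-Waugh identity (elastic net on
covariate-residualized trait and proteins is exactly the unpenalized-
covariate fit) with scikit-learn's coordinate descent; binomial traits use
statsmodels' elastic-net GLM with per-coefficient penalty weights and a
K-fold deviance-minimizing lambda path.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "ElasticNetConfig",
    "PanelSpec",
    "infer_family",
    "build_covariate_design",
    "select_features",
    "rank_and_truncate",
    "panel_zscore_stats",
    "composite_score",
    "high_impact_panel",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ElasticNetConfig:
    """Settings for penalized feature selection.

    ``alpha`` is the lasso/ridge mixing parameter (1 = lasso); the penalty
    strength lambda is chosen by K-fold cross-validation at the
    one-standard-error point (``lambda_rule="1se"``, the parsimonious
    glmnet convention; ``"min"`` selects at the deviance minimum). Covariates listed in ``covariates`` enter the selection
    model unpenalized. Proteins are standardized internally so the reported
    effects are on the standardized (scale-free) scale.
    """

    alpha: float = 0.5
    lambda_rule: str = "1se"
    n_cv_folds: int = 10
    n_lambdas: int = 50
    lambda_min_ratio: float = 1e-3
    standardize: bool = True
    covariates: Sequence[str] = ("age", "sex", "race")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")
        if self.n_cv_folds < 2:
            raise ValueError("n_cv_folds must be >= 2")


@dataclass
class PanelSpec:
    """A sign-filtered, effect-ordered protein panel for one trait."""

    trait: str
    polarity: str  # "negative-health" | "positive-health" | "any"
    proteins: list[str] = field(default_factory=list)
    effects: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.proteins)

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "polarity": self.polarity,
            "proteins": list(self.proteins),
            "effects": {p: float(e) for p, e in self.effects.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "PanelSpec":
        return cls(d["trait"], d["polarity"], list(d["proteins"]), dict(d["effects"]))


def infer_family(y: pd.Series) -> str:
    """'binomial' for a two-valued 0/1 trait, else 'gaussian'."""
    vals = pd.unique(y.dropna())
    if len(vals) <= 1:
        raise ValueError(f"trait {y.name!r} is constant")
    if len(vals) == 2 and set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}:
        return "binomial"
    return "gaussian"


def build_covariate_design(
    cohort: pd.DataFrame, covariates: Sequence[str], add_const: bool = True
) -> pd.DataFrame:
    """Numeric design matrix for covariates; categoricals become dummies."""
    cols = []
    for cov in covariates:
        s = cohort[cov]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=cov, drop_first=True, dtype=float)
            cols.append(dummies)
        else:
            cols.append(s.astype(float).to_frame())
    design = (
        pd.concat(cols, axis=1) if cols else pd.DataFrame(index=cohort.index)
    )
    if add_const:
        design.insert(0, "const", 1.0)
    return design


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sd = X.std(axis=0, ddof=0)
    keep = sd > 1e-12
    Xz = np.zeros_like(X)
    Xz[:, keep] = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return Xz, keep


def _select_gaussian(
    y: np.ndarray, Xz: np.ndarray, C: np.ndarray, config: ElasticNetConfig
) -> np.ndarray:
    # Frisch-Waugh: residualize trait and proteins on the unpenalized
    # covariates, then run plain elastic net -- identical optimum.
    beta_c, *_ = np.linalg.lstsq(C, y, rcond=None)
    y_r = y - C @ beta_c
    G, *_ = np.linalg.lstsq(C, Xz, rcond=None)
    X_r = Xz - C @ G
    cv = KFold(config.n_cv_folds, shuffle=True, random_state=config.seed)
    l1 = max(config.alpha, 1e-4)  # sklearn disallows a pure-ridge path
    model = ElasticNetCV(
        l1_ratio=l1,
        alphas=config.n_lambdas,
        eps=config.lambda_min_ratio,
        cv=cv,
        max_iter=5000,
    )
    model.fit(X_r, y_r)
    if config.lambda_rule == "1se":
        mse = model.mse_path_.mean(axis=1)
        se = model.mse_path_.std(axis=1, ddof=1) / math.sqrt(config.n_cv_folds)
        i_min = int(np.argmin(mse))
        limit = mse[i_min] + se[i_min]
        ok = np.where(mse <= limit)[0]
        lam = float(model.alphas_[ok.min()])  # alphas_ are descending
        refit = ElasticNetCV(l1_ratio=l1, alphas=[lam], cv=cv, max_iter=5000)
        refit.fit(X_r, y_r)
        return refit.coef_
    return model.coef_


def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-10, 1 - 1e-10)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def _fit_binomial_path(
    y: np.ndarray,
    D: np.ndarray,
    pen: np.ndarray,
    lambdas: np.ndarray,
    l1_wt: float,
) -> list[np.ndarray]:
    """Warm-started elastic-net fits along a descending lambda path."""
    fits = []
    start = None
    for lam in lambdas:
        res = sm.GLM(y, D, family=sm.families.Binomial()).fit_regularized(
            method="elastic_net",
            alpha=pen * lam,
            L1_wt=l1_wt,
            maxiter=80,
            start_params=start,
            cnvrg_tol=1e-6,
        )
        start = res.params
        fits.append(np.asarray(res.params))
    return fits


def _select_binomial(
    y: np.ndarray, Xz: np.ndarray, C: np.ndarray, config: ElasticNetConfig
) -> np.ndarray:
    n, p = Xz.shape
    D = np.column_stack([C, Xz])
    pen = np.r_[np.zeros(C.shape[1]), np.ones(p)]
    # lambda_max from the KKT gradient at the covariate-only fit
    mu0 = sm.GLM(y, C, family=sm.families.Binomial()).fit().fittedvalues
    grad = np.abs(Xz.T @ (y - mu0)) / n
    l1 = max(config.alpha, 1e-3)
    lam_max = float(grad.max() / l1) * 1.05 + 1e-12
    lambdas = np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambdas)

    folds = StratifiedKFold(
        config.n_cv_folds, shuffle=True, random_state=config.seed
    )
    dev = np.zeros((config.n_lambdas, config.n_cv_folds))
    for k, (tr, te) in enumerate(folds.split(Xz, y)):
        fits = _fit_binomial_path(y[tr], D[tr], pen, lambdas, config.alpha)
        for i, beta in enumerate(fits):
            eta = D[te] @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            dev[i, k] = _binomial_deviance(y[te], mu)
    mean_dev = dev.sum(axis=1)
    i_min = int(np.argmin(mean_dev))
    if config.lambda_rule == "1se":
        per_fold = dev
        se = per_fold.std(axis=1, ddof=1) * math.sqrt(config.n_cv_folds)
        limit = mean_dev[i_min] + se[i_min]
        i_min = int(np.where(mean_dev <= limit)[0].min())
    fits = _fit_binomial_path(y, D, pen, lambdas[: i_min + 1], config.alpha)
    return fits[-1][C.shape[1] :]


def select_features(
    cohort: pd.DataFrame,
    trait: str,
    candidate_pool: Iterable[str],
    config: ElasticNetConfig | None = None,
) -> pd.DataFrame:
    """Elastic-net selection of proteins for one trait.

    Returns the nonzero-coefficient proteins with their standardized
    penalized effects, sorted by descending absolute effect. The model
    family is inferred from the trait (gaussian for continuous, binomial
    for 0/1 traits); covariates are included unpenalized.
    """
    config = config or ElasticNetConfig()
    proteins = sorted(candidate_pool)
    missing = [p for p in proteins if p not in cohort.columns]
    if missing:
        raise KeyError(f"candidates absent from cohort: {missing[:5]} ...")
    y_s = cohort[trait]
    family = infer_family(y_s)
    y = y_s.to_numpy(dtype=float)
    X = cohort[proteins].to_numpy(dtype=float)
    Xz, keep = _standardize(X) if config.standardize else (X, np.ones(X.shape[1], bool))
    C = build_covariate_design(cohort, config.covariates).to_numpy(dtype=float)

    if family == "gaussian":
        coef = _select_gaussian(y, Xz, C, config)
    else:
        if len(np.unique(y)) < 2:
            raise ValueError("binary trait has fewer than 2 classes")
        coef = _select_binomial(y, Xz, C, config)
    coef = np.where(keep, coef, 0.0)
    nz = np.flatnonzero(np.abs(coef) > 1e-10)
    out = pd.DataFrame(
        {"protein": [proteins[i] for i in nz], "effect": coef[nz]}
    )
    return out.reindex(
        out["effect"].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)


def rank_and_truncate(
    selected: pd.DataFrame,
    trait: str,
    polarity: str,
    k: int = 25,
) -> PanelSpec:
    """Sign-filter by trait polarity, order by |effect|, keep at most ``k``.

    Negative-health traits keep positively associated proteins; positive-
    health traits keep inversely associated proteins; ``polarity="any"``
    keeps both signs (used e.g. for chronological-age panels). Ties in
    |effect| at the cut are broken by lexicographic protein identifier.
    """
    if polarity == "negative-health":
        kept = selected[selected["effect"] > 0]
    elif polarity == "positive-health":
        kept = selected[selected["effect"] < 0]
    elif polarity == "any":
        kept = selected
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    kept = kept.assign(abs_effect=kept["effect"].abs())
    kept = kept.sort_values(
        ["abs_effect", "protein"], ascending=[False, True], kind="stable"
    ).head(k)
    return PanelSpec(
        trait=trait,
        polarity=polarity,
        proteins=list(kept["protein"]),
        effects=dict(zip(kept["protein"], kept["effect"])),
    )


def panel_zscore_stats(cohort: pd.DataFrame, proteins: Sequence[str]) -> pd.DataFrame:
    """Per-protein cohort mean and sample SD (n-1) used for z-scoring."""
    X = cohort[list(proteins)]
    return pd.DataFrame({"mean": X.mean(), "sd": X.std(ddof=1)})


def composite_score(
    cohort: pd.DataFrame,
    panel: PanelSpec | Sequence[str],
    stats: pd.DataFrame | None = None,
) -> pd.Series:
    """Per-participant mean of z-scored abundances over the panel.

    ``stats`` may carry precomputed mean/sd columns (e.g. from a training
    split) so the score can be applied out of sample; by default z-scoring
    uses the scoring cohort itself (sample SD, n-1). Zero-variance proteins
    are excluded with a warning; an all-zero-variance panel is an error.
    """
    proteins = list(panel.proteins) if isinstance(panel, PanelSpec) else list(panel)
    if not proteins:
        raise ValueError("empty panel")
    if stats is None:
        stats = panel_zscore_stats(cohort, proteins)
    usable = [p for p in proteins if stats.loc[p, "sd"] > 1e-12]
    dropped = set(proteins) - set(usable)
    if dropped:
        logger.warning("excluding %d zero-variance proteins from score", len(dropped))
    if not usable:
        raise ValueError("all panel proteins have zero variance")
    X = cohort[usable]
    z = (X - stats.loc[usable, "mean"]) / stats.loc[usable, "sd"]
    return z.mean(axis=1).rename("score")


def high_impact_panel(panels: Mapping[str, PanelSpec]) -> set[str]:
    """Proteins selected for at least half (ceiling) of the traits."""
    if len(panels) < 2:
        raise ValueError("need panels for at least 2 traits")
    threshold = math.ceil(len(panels) / 2)
    counts: dict[str, int] = {}
    for spec in panels.values():
        for prot in set(spec.proteins):
            counts[prot] = counts.get(prot, 0) + 1
    return {p for p, c in counts.items() if c >= threshold}
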