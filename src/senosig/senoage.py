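"""Cell-type seno-ages and residual seno-age gaps.

A seno-age model is an ordinary least-squares regression of chronological
age on the abundances of a signature's panel proteins (selection and
estimation are separated: the panel comes from elastic net, the age model
is unpenalized). The per-participant *seno-age gap* is the residual of the
predicted seno-age about its own trend line on chronological age, so gaps
are mean-zero and uncorrelated with age by construction: a positive gap
marks a participant whose circulating signature makes them look older than
their years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .burden_scoring import PanelSpec
from .trait_association import TraitModelResult, fit_trait_model

__all__ = [
    "SenoAgeModel",
    "fit_senoage_model",
    "compute_gap",
    "gap_trait_association",
    "senoage_correlation_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class SenoAgeModel:
    """Fitted linear age model on a signature's protein panel."""

    signature: str
    proteins: list[str]
    coef: pd.Series  # index: ["const", *proteins]
    rank: int

    def predict(self, cohort: pd.DataFrame) -> pd.Series:
        X = np.column_stack(
            [np.ones(len(cohort)), cohort[self.proteins].to_numpy(float)]
        )
        return pd.Series(
            X @ self.coef.to_numpy(), index=cohort.index, name="seno_age"
        )


def fit_senoage_model(
    cohort: pd.DataFrame,
    panel: PanelSpec | Sequence[str],
    signature: str | None = None,
    age_col: str = "age",
) -> SenoAgeModel:
    """Least squares of chronological age on the panel protein abundances.

    A rank-deficient design (collinear proteins) is resolved by the
    minimum-norm solution with the deficiency logged, never silently.
    """
    if isinstance(panel, PanelSpec):
        proteins = list(panel.proteins)
        signature = signature or panel.trait
    else:
        proteins = list(panel)
        signature = signature or "signature"
    if not proteins:
        raise ValueError("empty panel")
    X = np.column_stack([np.ones(len(cohort)), cohort[proteins].to_numpy(float)])
    y = cohort[age_col].to_numpy(float)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        logger.warning(
            "seno-age design for %s is rank deficient (%d < %d); "
            "minimum-norm coefficients used",
            signature,
            rank,
            X.shape[1],
        )
    coef = pd.Series(beta, index=["const", *proteins])
    return SenoAgeModel(signature, proteins, coef, int(rank))


def compute_gap(
    cohort: pd.DataFrame,
    model: SenoAgeModel,
    age_col: str = "age",
    trend: str = "linear",
) -> pd.DataFrame:
    """Seno-ages and residual gaps about the age trend line.

    The trend line is the OLS regression of predicted seno-age on
    chronological age, fit on the scoring cohort (so a transferred model's
    gaps are re-centered within the target study); ``trend="lowess"``
    substitutes a lowess smoother. Gaps are mean-zero and, for the linear
    trend, exactly uncorrelated with age.
    """
    pred = model.predict(cohort)
    if pred.std(ddof=0) < 1e-12:
        raise ValueError("predicted seno-age is constant")
    age = cohort[age_col].to_numpy(float)
    if trend == "linear":
        D = np.column_stack([np.ones(len(age)), age])
        beta, *_ = np.linalg.lstsq(D, pred.to_numpy(), rcond=None)
        fitted = D @ beta
    elif trend == "lowess":
        from statsmodels.nonparametric.smoothers_lowess import lowess

        sm_fit = lowess(pred.to_numpy(), age, frac=0.6, return_sorted=False)
        fitted = sm_fit
    else:
        raise ValueError(f"unknown trend {trend!r}")
    gap = pred.to_numpy() - fitted
    return pd.DataFrame(
        {
            "signature": model.signature,
            "seno_age": pred.to_numpy(),
            "gap": gap,
        },
        index=cohort.index,
    )


def gap_trait_association(
    gaps: pd.Series | pd.DataFrame,
    cohort: pd.DataFrame,
    trait: str,
    covariates: Sequence[str] = ("sex", "race"),
    include_age: bool = False,
) -> TraitModelResult:
    """Trait model with the seno-age gap as predictor.

    Chronological age is excluded from the covariates by default because
    the gap is already age-decorrelated on the fitting cohort;
    ``include_age=True`` re-includes it.
    """
    gap = gaps["gap"] if isinstance(gaps, pd.DataFrame) else gaps
    gap = gap.rename("gap")
    covs = list(covariates)
    if include_age and "age" not in covs:
        covs.append("age")
    return fit_trait_model(cohort, trait, gap, covariates=covs)


def senoage_correlation_matrix(
    records: Mapping[str, pd.Series] | pd.DataFrame, column: str = "gap"
) -> pd.DataFrame:
    """Signature-by-signature Pearson correlations on shared participants.

    ``records`` is either a mapping of signature label to a participant-
    indexed Series, or a long DataFrame with ``signature`` plus a value
    column (``gap`` or ``seno_age``).
    """
    if isinstance(records, pd.DataFrame):
        wide = records.pivot_table(
            index=records.index, columns="signature", values=column
        )
    else:
        wide = pd.DataFrame({k: v for k, v in records.items()})
    wide = wide.dropna()
    if wide.shape[1] < 2:
        raise ValueError("need at least 2 signatures")
    if len(wide) < 3:
        raise ValueError("fewer than 3 shared participants")
    return wide.corr(method="pearson")
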