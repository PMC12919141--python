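"""Left-truncated survival models for death and disease onset.

Age — not follow-up time — is the time scale: a participant enters the
risk set at the age of their proteomics measurement (delayed entry) and
exits at the age of event or last follow-up, matching the study design
``Surv(entry_age, exit_age, status) ~ predictor + strata(sex) +
strata(race)``. Fits use the stratified Cox partial likelihood with the
Efron tie correction; the proportional-hazards assumption is checked by a
score test on scaled Schoenfeld residuals; lifetime trajectories contrast
the top and bottom quartile of a composite burden score via delayed-entry
Kaplan-Meier cumulative incidence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

__all__ = [
    "CoxResult",
    "fit_cox_left_truncated",
    "schoenfeld_test",
    "quartile_trajectories",
]

logger = logging.getLogger(__name__)


@dataclass
class CoxResult:
    predictor: str
    log_hr: float
    se: float
    p_value: float
    n_events: int
    n: int
    monotone_flag: bool = False
    schoenfeld_p: float | None = None
    fitter: CoxPHFitter | None = None
    data: pd.DataFrame | None = None

    def summary(self) -> str:
        hr = np.exp(self.log_hr)
        txt = (
            f"Cox (delayed entry): {self.predictor} log-HR {self.log_hr:+.4f} "
            f"(HR {hr:.3f}, se {self.se:.4f}, p {self.p_value:.3g}), "
            f"{self.n_events}/{self.n} events"
        )
        if self.monotone_flag:
            txt += " [monotone likelihood flagged]"
        if self.schoenfeld_p is not None:
            txt += f"; Schoenfeld p {self.schoenfeld_p:.3g}"
        return txt


def _check_records(records: pd.DataFrame) -> None:
    if (records["exit_age"] <= records["entry_age"]).any():
        raise ValueError("every record needs exit_age > entry_age")
    if records["event_status"].sum() == 0:
        raise ValueError("no events in the records")


def fit_cox_left_truncated(
    records: pd.DataFrame,
    predictor,
    strata: Sequence[str] = ("sex", "race"),
) -> CoxResult:
    """Stratified Cox fit with delayed-entry risk sets on the age scale.

    ``records`` must carry ``entry_age``, ``exit_age``, ``event_status``
    and the strata columns; ``predictor`` is a column name or a
    participant-aligned Series (e.g. a composite burden score). A monotone
    partial likelihood (infinite estimate) is flagged, not raised.
    """
    _check_records(records)
    if isinstance(predictor, str):
        name, x = predictor, records[predictor]
    else:
        x = pd.Series(predictor).reindex(records.index)
        name = x.name or "score"
    if x.std(ddof=0) < 1e-12:
        raise ValueError("predictor is constant")
    df = pd.DataFrame(
        {
            "entry_age": records["entry_age"].astype(float),
            "exit_age": records["exit_age"].astype(float),
            "event_status": records["event_status"].astype(int),
            name: x.astype(float),
        }
    )
    strata = [s for s in strata if s in records.columns]
    for s in strata:
        df[s] = records[s].to_numpy()
    cph = CoxPHFitter()
    monotone = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(
            df,
            duration_col="exit_age",
            event_col="event_status",
            entry_col="entry_age",
            strata=strata or None,
        )
        monotone = any("convergence" in str(w.message).lower() for w in caught)
    se = float(cph.standard_errors_[name])
    if not np.isfinite(se) or se > 1e2:
        monotone = True
    return CoxResult(
        predictor=name,
        log_hr=float(cph.params_[name]),
        se=se,
        p_value=float(cph.summary.loc[name, "p"]),
        n_events=int(df["event_status"].sum()),
        n=len(df),
        monotone_flag=monotone,
        fitter=cph,
        data=df,
    )


def _schoenfeld_residuals(
    df: pd.DataFrame, name: str, beta: float, strata: Sequence[str]
) -> pd.DataFrame:
    """Per-event Schoenfeld residuals with delayed-entry risk sets.

    At each event age ``a`` within a stratum, the risk set comprises
    participants with ``entry_age < a <= exit_age``; the residual is the
    event's covariate minus the hazard-weighted risk-set mean (Breslow
    convention for the rare continuous-age ties).
    """
    rows = []
    groups = df.groupby(list(strata), observed=True) if strata else [(None, df)]
    for _, g in groups:
        x = g[name].to_numpy(float)
        entry = g["entry_age"].to_numpy(float)
        exit_ = g["exit_age"].to_numpy(float)
        ev = g["event_status"].to_numpy(int).astype(bool)
        w = np.exp(beta * x)
        for a, xi in zip(exit_[ev], x[ev]):
            at_risk = (entry < a) & (a <= exit_)
            ww = w[at_risk]
            xx = x[at_risk]
            xbar = float((ww * xx).sum() / ww.sum())
            var = float((ww * xx**2).sum() / ww.sum() - xbar**2)
            rows.append({"age": a, "residual": xi - xbar, "variance": var})
    return pd.DataFrame(rows).sort_values("age", ignore_index=True)


def schoenfeld_test(result: CoxResult, time_transform: str = "identity") -> float:
    """Proportional-hazards score test on Schoenfeld residuals.

    Score test of association between the per-event residuals and (a
    transform of) event age, after Grambsch & Therneau; small p-values
    indicate that the predictor's hazard ratio drifts with age. Computed
    in-package because delayed-entry residuals are unavailable upstream;
    the identity transform is the default, ``"km"`` uses the left-
    continuous Kaplan-Meier survival of event ages.
    """
    if result.fitter is None or result.data is None:
        raise ValueError("result does not carry a fitted model")
    if result.n_events < 2:
        raise ValueError("need at least 2 events for the Schoenfeld test")
    strata = [
        s for s in result.data.columns
        if s not in ("entry_age", "exit_age", "event_status", result.predictor)
    ]
    res = _schoenfeld_residuals(
        result.data, result.predictor, result.log_hr, strata
    )
    if time_transform == "identity":
        g = res["age"].to_numpy()
    elif time_transform == "km":
        km = KaplanMeierFitter().fit(
            result.data["exit_age"],
            result.data["event_status"],
            entry=result.data["entry_age"],
        )
        g = 1.0 - km.survival_function_at_times(res["age"]).to_numpy()
    else:
        raise ValueError(f"unknown time transform {time_transform!r}")
    r = res["residual"].to_numpy()
    v_mean = float(res["variance"].mean())
    g_c = g - g.mean()
    denom = v_mean * float((g_c**2).sum())
    if denom <= 0:
        raise ValueError("degenerate residual variance; test undefined")
    chi2 = float((g_c @ r) ** 2 / denom)
    p = float(stats.chi2.sf(chi2, df=1))
    result.schoenfeld_p = p
    return p


def quartile_trajectories(
    records: pd.DataFrame, score: pd.Series
) -> dict:
    """Delayed-entry Kaplan-Meier cumulative incidence, top vs bottom quartile.

    Participants are ranked by score with ties broken by identifier, split
    into quartiles, and the first (lowest) and fourth (highest) quartile
    get a delayed-entry Kaplan-Meier fit on the age scale; curves are
    reported as cumulative incidence ``1 - S(age)`` with numbers at risk.
    For onset endpoints, records of participants already affected at entry
    should be excluded by the caller before ranking.
    """
    score = pd.Series(score).reindex(records.index)
    if len(score) < 4:
        raise ValueError("need at least 4 scored participants")
    if score.std(ddof=0) < 1e-12:
        raise ValueError("all scores identical; quartiles undefined")
    if (records["exit_age"] <= records["entry_age"]).any():
        raise ValueError("every record needs exit_age > entry_age")
    order = np.lexsort((score.index.to_numpy(), score.to_numpy()))
    rank = np.empty(len(score), dtype=int)
    rank[order] = np.arange(len(score))
    quartile = np.minimum(rank * 4 // len(score), 3)
    labels = {0: "Q1 (lowest)", 3: "Q4 (highest)"}
    frames, sizes = [], {}
    for q, label in labels.items():
        grp = records.loc[quartile == q]
        sizes[label] = len(grp)
        km = KaplanMeierFitter()
        km.fit(
            durations=grp["exit_age"],
            event_observed=grp["event_status"],
            entry=grp["entry_age"],
            label=label,
        )
        surv = km.survival_function_
        at_risk = km.event_table["at_risk"].reindex(surv.index).ffill()
        frames.append(
            pd.DataFrame(
                {
                    "age": surv.index.to_numpy(float),
                    "group": label,
                    "cum_incidence": 1.0 - surv[label].to_numpy(float),
                    "n_at_risk": at_risk.to_numpy(float),
                }
            )
        )
    return {"curves": pd.concat(frames, ignore_index=True), "group_sizes": sizes}
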