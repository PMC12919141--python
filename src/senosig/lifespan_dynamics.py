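"""Nonlinear lifespan dynamics of protein abundances.

Implements the sliding-window differential-abundance scan (DE-SWAN style):
at each 1-year center ``t`` between 60 and 80, participants aged
``[t-10, t)`` are compared with those aged ``[t, t+10)`` via a covariate-
adjusted linear model per protein, with Benjamini-Hochberg correction
across proteins within each center. A participant aged exactly ``t``
belongs to the upper window (half-open convention). Before scanning, the
cohort is decade-balanced by random downsampling (equal numbers per decade
of life, split evenly by sex) and the balance of the subsample against the
eligible pool is audited with standardized mean differences (SMD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .burden_scoring import build_covariate_design

__all__ = [
    "WindowSpec",
    "DeswanResult",
    "balanced_downsample",
    "deswan_scan",
    "peak_center",
    "sex_stratified_scan",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window layout: centers and half-width in years.

    At center ``t`` the lower window is ``[t - width, t)`` and the upper
    window ``[t, t + width)``: contiguous, half-open and disjoint, with a
    participant at exactly ``t`` assigned upward.
    """

    centers: Sequence[float] = tuple(range(60, 81))
    width: float = 10.0

    def assign(self, ages: np.ndarray, center: float) -> np.ndarray:
        """Window membership at ``center``: -1 lower, +1 upper, 0 outside."""
        out = np.zeros(len(ages), dtype=int)
        out[(ages >= center - self.width) & (ages < center)] = -1
        out[(ages >= center) & (ages < center + self.width)] = 1
        return out


@dataclass
class DeswanResult:
    counts: pd.DataFrame  # per center (x group): n_elevated, n_depressed, n
    records: pd.DataFrame  # long: center, protein, coef, p, q, direction
    skipped: list[float] = field(default_factory=list)


def balanced_downsample(
    cohort: pd.DataFrame,
    age_range: tuple[float, float] = (50.0, 90.0),
    n_per_decade: int = 120,
    sex_balance: float = 0.5,
    seed: int = 0,
    smd_covariates: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Equal-size random subsample per decade of life, split evenly by sex.

    Sampling is without replacement within each (decade, sex) stratum; an
    undersized stratum raises an error naming it. Returns the subsample and
    a balance report of standardized mean differences between the subsample
    and the eligible pool for every numeric covariate (or the columns in
    ``smd_covariates``).
    """
    lo, hi = age_range
    eligible = cohort[(cohort["age"] >= lo) & (cohort["age"] < hi)]
    n_male = int(round(n_per_decade * sex_balance))
    quota = {1: n_male, 0: n_per_decade - n_male}
    rng = np.random.default_rng(seed)
    chosen: list[pd.Index] = []
    for dec_lo in np.arange(lo, hi, 10.0):
        decade = eligible[(eligible["age"] >= dec_lo) & (eligible["age"] < dec_lo + 10)]
        for sex_val, n_need in quota.items():
            stratum = decade[decade["sex"] == sex_val]
            if len(stratum) < n_need:
                raise ValueError(
                    f"stratum decade [{dec_lo:.0f},{dec_lo + 10:.0f}) sex={sex_val} "
                    f"has {len(stratum)} eligible participants, need {n_need}"
                )
            idx = np.sort(rng.choice(len(stratum), size=n_need, replace=False))
            chosen.append(stratum.index[idx])
    sub = cohort.loc[chosen[0].append(chosen[1:])]

    if smd_covariates is None:
        smd_covariates = [
            c
            for c in cohort.columns
            if cohort[c].dtype.kind in "fiu" and not c.startswith("P")
        ]
    rows = []
    for cov in smd_covariates:
        ms, mp = sub[cov].mean(), eligible[cov].mean()
        vs, vp = sub[cov].var(ddof=1), eligible[cov].var(ddof=1)
        pooled = np.sqrt((vs + vp) / 2.0)
        rows.append({"covariate": cov, "smd": (ms - mp) / pooled if pooled > 0 else 0.0})
    return sub, pd.DataFrame(rows)


def _window_fit(
    Y: np.ndarray, indicator: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Multi-protein OLS of abundance on the window indicator + covariates."""
    n = len(indicator)
    D = np.column_stack([np.ones(n), indicator.astype(float), C])
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ beta
    dof = n - D.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.pinv(D.T @ D)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
    tval = beta[1] / se
    pval = 2.0 * stats.t.sf(np.abs(tval), dof)
    return beta[1], pval


def deswan_scan(
    cohort: pd.DataFrame,
    proteins: Sequence[str],
    windows: WindowSpec | None = None,
    covariates: Sequence[str] = ("sex",),
    q_threshold: float = 0.05,
    groups: Mapping[str, set] | None = None,
) -> DeswanResult:
    """Counts of elevated/depressed proteins at each sliding-window center.

    "Elevated" at center ``t`` means a positive upper-vs-lower-window
    indicator coefficient with BH-adjusted p below ``q_threshold``
    (adjustment across proteins, within each center). ``groups`` optionally
    maps labels (e.g. SAP / non-SAP) to protein sets for grouped counts;
    otherwise all proteins are counted as one group.
    """
    windows = windows or WindowSpec()
    proteins = list(proteins)
    ages = cohort["age"].to_numpy(float)
    groups = groups or {"all": set(proteins)}
    count_rows, rec_frames, skipped = [], [], []
    for center in windows.centers:
        member = windows.assign(ages, center)
        mask = member != 0
        if not (member == -1).any() or not (member == 1).any():
            logger.warning("center %s skipped: empty window", center)
            skipped.append(center)
            continue
        sub = cohort.loc[mask]
        C = (
            build_covariate_design(sub, covariates, add_const=False).to_numpy(float)
            if covariates
            else np.empty((int(mask.sum()), 0))
        )
        Y = sub[proteins].to_numpy(float)
        coef, pval = _window_fit(Y, (member[mask] == 1), C)
        qval = multipletests(pval, method="fdr_bh")[1]
        rec = pd.DataFrame(
            {
                "center": center,
                "protein": proteins,
                "coef": coef,
                "p_value": pval,
                "q_value": qval,
            }
        )
        rec["direction"] = np.select(
            [(rec.coef > 0) & (rec.q_value < q_threshold),
             (rec.coef < 0) & (rec.q_value < q_threshold)],
            ["elevated", "depressed"],
            default="ns",
        )
        rec_frames.append(rec)
        for gname, gset in groups.items():
            g = rec[rec["protein"].isin(gset)]
            count_rows.append(
                {
                    "center": center,
                    "group": gname,
                    "n_elevated": int((g.direction == "elevated").sum()),
                    "n_depressed": int((g.direction == "depressed").sum()),
                    "n_participants": int(mask.sum()),
                }
            )
    counts = pd.DataFrame(count_rows)
    records = (
        pd.concat(rec_frames, ignore_index=True) if rec_frames else pd.DataFrame()
    )
    return DeswanResult(counts, records, skipped)


def peak_center(
    result: DeswanResult, group: str | None = None
) -> tuple[float | None, bool]:
    """Center with the maximal elevated count; ties go to the smallest.

    Returns ``(center, tied)``; ``(None, True)`` when no center has any
    elevated protein (flat null) or nothing was scanned.
    """
    counts = result.counts
    if counts.empty:
        return None, True
    if group is not None:
        counts = counts[counts["group"] == group]
    per_center = counts.groupby("center")["n_elevated"].sum()
    peak_val = per_center.max()
    if peak_val == 0:
        return None, True
    winners = per_center[per_center == peak_val].index
    return float(winners.min()), len(winners) > 1


def sex_stratified_scan(
    cohort: pd.DataFrame,
    proteins: Sequence[str],
    windows: WindowSpec | None = None,
    covariates: Sequence[str] = (),
    q_threshold: float = 0.05,
    groups: Mapping[str, set] | None = None,
) -> dict:
    """Run the sliding-window scan independently per sex with peak ages.

    Returns ``{"F": DeswanResult, "M": ..., "peaks": {"F": (age, tied), ...}}``.
    The sex covariate is dropped within strata; extra covariates pass
    through.
    """
    out: dict = {"peaks": {}}
    for label, sex_val in (("F", 0), ("M", 1)):
        sub = cohort[cohort["sex"] == sex_val]
        res = deswan_scan(sub, proteins, windows, covariates, q_threshold, groups)
        out[label] = res
        out["peaks"][label] = peak_center(res)
    return out
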