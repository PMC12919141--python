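"""Derivation of senescence protein signatures from a multi-induction catalog.

The catalog records, per protein, cell type and induction method, a log2
fold-change (senescent over proliferating) and a Benjamini-Hochberg adjusted
p-value. From those records this module derives:

* a three-way senescence status per protein (SAP / non-SAP / inconclusive),
* per-cell-type signatures with their mean qualifying log2FC,
* cell-type-exclusive signatures (SAP in one cell type of a chosen universe
  and in no other),
* core signatures (SAP in at least ``k_core`` cell types of the universe),
* a status-by-study detection cross-tabulation with Fisher exact tests,
* tissue-atlas support proportions for a signature.

A protein is "qualifyingly elevated" in a (cell type, induction) when its
log2FC is strictly positive and its adjusted p-value is below 0.05. The
default membership rule requires ionizing radiation (IR) plus at least one
chemical inducer; ``rule="any-two"`` relaxes this to any two inductions.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "differential_abundance",
    "catalog_differential_records",
    "classify_senescence_status",
    "cell_type_signature",
    "exclusive_signature",
    "core_signature",
    "detection_crosstab",
    "fisher_exact_rxc",
    "tissue_support_proportion",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05
IR_LABEL = "IR"


def differential_abundance(
    proliferating: pd.DataFrame,
    senescent: pd.DataFrame,
    cell_type: str = "",
    induction: str = "",
) -> pd.DataFrame:
    """Per-protein Welch differential abundance between two replicate arms.

    Both inputs are protein x replicate matrices of log2 intensities with an
    identical protein index. Returns one record per protein with columns
    ``protein``, ``cell_type``, ``induction``, ``log2fc`` (mean senescent
    minus mean proliferating), ``p_value`` (two-sided Welch t) and ``p_adj``
    (BH across all proteins of this stratum).

    Proteins with zero variance in both arms get p = 1 when the means are
    equal (no evidence either way) and p = 0 when they differ exactly.
    """
    if proliferating.shape[1] < 2 or senescent.shape[1] < 2:
        raise ValueError("need at least 2 replicates per arm")
    if not proliferating.index.equals(senescent.index):
        raise ValueError("mismatched protein sets between arms")

    pro = proliferating.to_numpy(dtype=float)
    sen = senescent.to_numpy(dtype=float)
    log2fc = sen.mean(axis=1) - pro.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(sen, pro, axis=1, equal_var=False)
        pvals = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(pvals)
    pvals[degenerate & (log2fc == 0.0)] = 1.0
    pvals[degenerate & (log2fc != 0.0)] = 0.0
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "protein": proliferating.index,
            "cell_type": cell_type,
            "induction": induction,
            "log2fc": log2fc,
            "p_value": pvals,
            "p_adj": p_adj,
        }
    ).reset_index(drop=True)


def catalog_differential_records(catalog) -> pd.DataFrame:
    """Run :func:`differential_abundance` over every catalog condition."""
    frames = [
        differential_abundance(
            catalog.proliferating[key], catalog.senescent[key], key[0], key[1]
        )
        for key in catalog.conditions
    ]
    return pd.concat(frames, ignore_index=True)


def _qualifying(records: pd.DataFrame, alpha: float = ALPHA) -> pd.DataFrame:
    return records[(records["log2fc"] > 0.0) & (records["p_adj"] < alpha)]


def _members_by_cell_type(
    records: pd.DataFrame, rule: str, alpha: float
) -> dict[str, set[str]]:
    """Proteins qualifying in >=2 inductions per cell type under ``rule``."""
    qual = _qualifying(records, alpha)
    members: dict[str, set[str]] = {
        ct: set() for ct in records["cell_type"].unique()
    }
    if qual.empty:
        return members
    grouped = qual.groupby(["cell_type", "protein"])["induction"].agg(set)
    for (ct, prot), inductions in grouped.items():
        if rule == "ir-plus-chemical":
            ok = IR_LABEL in inductions and len(inductions - {IR_LABEL}) >= 1
        elif rule == "any-two":
            ok = len(inductions) >= 2
        else:
            raise ValueError(f"unknown rule {rule!r}")
        if ok:
            members[ct].add(prot)
    return members


def classify_senescence_status(
    records: pd.DataFrame,
    rule: str = "ir-plus-chemical",
    alpha: float = ALPHA,
    universe: Iterable[str] | None = None,
) -> pd.Series:
    """Partition the protein universe into SAP / non-SAP / inconclusive.

    SAP: qualifyingly elevated in two induction methods (per ``rule``) for
    at least one cell type. Non-SAP: not qualifyingly elevated anywhere.
    Inconclusive: elevated somewhere, but never in two inductions of the
    same cell type. Every protein with records gets exactly one status;
    proteins of ``universe`` without records are excluded with a warning.
    """
    if records["cell_type"].nunique() < 1 or records["induction"].nunique() < 2:
        raise ValueError("records must cover >=1 cell type with >=2 inductions")
    recorded = set(records["protein"])
    if universe is not None:
        missing = set(universe) - recorded
        if missing:
            logger.warning(
                "%d proteins of the universe have no records and are excluded",
                len(missing),
            )
    members = _members_by_cell_type(records, rule, alpha)
    saps = set().union(*members.values()) if members else set()
    elevated_somewhere = set(_qualifying(records, alpha)["protein"])
    status = pd.Series("non-SAP", index=sorted(recorded), name="status", dtype=object)
    status[status.index.isin(elevated_somewhere)] = "inconclusive"
    status[status.index.isin(saps)] = "SAP"
    return status


def cell_type_signature(
    records: pd.DataFrame,
    cell_type: str,
    rule: str = "ir-plus-chemical",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Signature of one cell type with the mean qualifying log2FC.

    Members satisfy the two-induction rule for ``cell_type``; the reported
    log2FC is the mean over that protein's qualifying inductions there.
    """
    cts = set(records["cell_type"].unique())
    if cell_type not in cts:
        raise KeyError(f"unknown cell type {cell_type!r}")
    sub = records[records["cell_type"] == cell_type]
    if sub["induction"].nunique() < 2:
        raise ValueError(f"cell type {cell_type!r} has fewer than 2 inductions")
    members = _members_by_cell_type(sub, rule, alpha)[cell_type]
    qual = _qualifying(sub, alpha)
    qual = qual[qual["protein"].isin(members)]
    out = (
        qual.groupby("protein")["log2fc"].mean().rename("mean_log2fc").reset_index()
    )
    return out.sort_values("protein", ignore_index=True)


def exclusive_signature(
    signatures: Mapping[str, Iterable[str]], cell_type: str
) -> set[str]:
    """Members of ``cell_type``'s signature that are in no other signature.

    ``signatures`` maps each cell type of the chosen universe to its SAP
    set; exclusivity is defined within that universe.
    """
    if cell_type not in signatures:
        raise KeyError(f"cell type {cell_type!r} not in the signature universe")
    own = set(signatures[cell_type])
    others: set[str] = set()
    for ct, members in signatures.items():
        if ct != cell_type:
            others |= set(members)
    return own - others


def core_signature(
    signatures: Mapping[str, Iterable[str]],
    k_core: int,
    universe: Iterable[str] | None = None,
) -> set[str]:
    """Proteins that are SAPs in at least ``k_core`` cell types.

    ``universe`` restricts which cell types count toward membership
    (default: all keys of ``signatures``).
    """
    if k_core < 1:
        raise ValueError("k_core must be >= 1")
    cts = list(universe) if universe is not None else list(signatures)
    if k_core > len(cts):
        raise ValueError("k_core exceeds the cell-type universe size")
    counts: dict[str, int] = {}
    for ct in cts:
        for prot in signatures[ct]:
            counts[prot] = counts.get(prot, 0) + 1
    return {prot for prot, c in counts.items() if c >= k_core}


def fisher_exact_rxc(table: np.ndarray) -> float:
    """Exact conditional test p-value for an r x 2 contingency table.

    Enumerates all tables with the observed margins (the first column's
    free cells; the second column follows) and sums the probabilities of
    tables no more probable than the observed one, the standard
    two-sided Fisher exact convention. Probabilities use the multivariate
    hypergeometric mass via log-gamma. Suitable for the small r (<= ~4)
    and moderate counts of status-by-study tables.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or table.shape[1] != 2:
        raise ValueError("expected an r x 2 table")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    total = int(table.sum())
    if total == 0:
        return 1.0

    const = gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(total + 1)

    def logp(first_col: np.ndarray) -> float:
        cells = np.stack([first_col, rows - first_col])
        return float(const - gammaln(cells + 1).sum())

    obs_logp = logp(table[:, 0])
    r = len(rows)

    probs: list[float] = []

    def rec(i: int, remaining: int, acc: list[int]) -> None:
        if i == r - 1:
            if remaining <= rows[i]:
                probs.append(logp(np.array(acc + [remaining])))
            return
        # feasibility bounds for cell (i, 0)
        lo = max(0, remaining - int(rows[i + 1 :].sum()))
        hi = min(int(rows[i]), remaining)
        for v in range(lo, hi + 1):
            rec(i + 1, remaining - v, acc + [v])

    rec(0, int(cols[0]), [])
    logps = np.array(probs)
    # tables at most as probable as observed, with tolerance for fp ties
    mask = logps <= obs_logp + 1e-9
    return float(min(1.0, np.exp(logps[mask]).sum()))


def detection_crosstab(
    status: pd.Series,
    panel_a: Iterable[str],
    panel_b: Iterable[str],
    labels: tuple[str, str] = ("study_A", "study_B"),
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Status-by-study counts of catalog proteins detected in each panel.

    Returns the 3 x 2 contingency table (rows SAP / non-SAP / inconclusive,
    columns the two studies) and a dict of Fisher exact p-values: the
    overall r x 2 test plus each pairwise 2 x 2 status comparison.
    """
    panel_a, panel_b = set(panel_a), set(panel_b)
    if not panel_a or not panel_b:
        raise ValueError("panels must be non-empty")
    order = ["SAP", "non-SAP", "inconclusive"]
    counts = {
        labels[0]: [sum(1 for p in panel_a if status.get(p) == s) for s in order],
        labels[1]: [sum(1 for p in panel_b if status.get(p) == s) for s in order],
    }
    table = pd.DataFrame(counts, index=order)
    arr = table.to_numpy()
    pvals = {"overall": fisher_exact_rxc(arr)}
    for i, s in enumerate(order):
        sub = np.array(
            [arr[i], arr.sum(axis=0) - arr[i]]
        )
        pvals[s] = float(stats.fisher_exact(sub)[1])
    return table, pvals


def tissue_support_proportion(
    signature: Iterable[str], atlas: pd.DataFrame
) -> pd.Series:
    """Per-section proportion of signature proteins at medium/high level.

    ``atlas`` is long-format with columns ``protein``, ``section``,
    ``level``. The proportion for a section is computed over the signature
    proteins present in the atlas; sections are returned ranked descending.
    """
    signature = set(signature)
    if not signature:
        raise ValueError("empty signature")
    sub = atlas[atlas["protein"].isin(signature)]
    if sub.empty:
        raise ValueError("signature and atlas share no proteins")
    is_mh = sub["level"].isin(["medium", "high"])
    prop = is_mh.groupby(sub["section"]).mean()
    return prop.sort_values(ascending=False, kind="stable").rename("support")
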