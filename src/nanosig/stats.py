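"""Concordance and group-comparison statistics.

Pairwise-complete Spearman matrices over scores/subscores, Cohen's kappa
on tertile-dichotomized scores (top third "high" vs the rest) and on
multi-class subtype calls, exact/approximate Mann-Whitney tests, and
per-gene two-group comparisons with optional Benjamini-Hochberg control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "spearman_matrix",
    "tertile_dichotomize",
    "cohens_kappa",
    "mann_whitney",
    "group_comparisons",
    "per_gene_comparison",
]

#: combined sample size at or below which the exact Mann-Whitney null is used
EXACT_SWITCHOVER = 12


def spearman_matrix(scores: pd.DataFrame, min_n: int = 3):
    """Pairwise-complete Spearman correlation over score columns.

    Returns ``(rho, n)`` frames; pairs with fewer than ``min_n`` complete
    observations are NaN with a warning.
    """
    cols = list(scores.columns)
    rho = pd.DataFrame(np.nan, index=cols, columns=cols)
    nmat = pd.DataFrame(0, index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i:]:
            sub = scores[[a, b]].dropna()
            nmat.loc[a, b] = nmat.loc[b, a] = len(sub)
            if len(sub) < min_n:
                logger.warning("spearman %s vs %s: only %d complete pairs", a, b, len(sub))
                continue
            if a == b:
                r = 1.0
            else:
                r = float(sps.spearmanr(sub[a], sub[b]).statistic)
            rho.loc[a, b] = rho.loc[b, a] = r
    return rho, nmat


def tertile_dichotomize(score: pd.Series) -> pd.Series:
    """Label the ceil(n/3) largest non-missing values "high", the rest
    "intermediate-low". Ties at the cut are resolved by stable sample-id
    order (warned); an all-constant vector is entirely intermediate-low."""
    vals = score.dropna()
    if len(vals) < 3:
        raise ValueError("tertile dichotomization needs >= 3 non-missing values")
    if vals.nunique() == 1:
        logger.warning("constant score %s: no sample labelled high", score.name)
        labels = pd.Series("intermediate-low", index=vals.index)
    else:
        k = math.ceil(len(vals) / 3)
        order = vals.to_frame("v").reset_index()
        idcol = order.columns[0]
        order = order.sort_values(["v", idcol], ascending=[False, True])
        cut = order["v"].iloc[k - 1]
        if (order["v"] == cut).sum() > 1 and k < len(order) and order["v"].iloc[k] == cut:
            logger.warning("ties at the tertile cut of %s resolved by sample order",
                           score.name)
        high = set(order[idcol].iloc[:k])
        labels = pd.Series(
            ["high" if i in high else "intermediate-low" for i in vals.index],
            index=vals.index,
        )
    return labels.reindex(score.index).rename(score.name)


def cohens_kappa(labels_a, labels_b) -> float:
    """Unweighted Cohen's kappa over any number of categories.

    Pairs with a missing label on either side are dropped. When both
    raters are constant and identical (chance agreement 1) kappa is 1 by
    convention.
    """
    a = pd.Series(list(labels_a)).reset_index(drop=True)
    b = pd.Series(list(labels_b)).reset_index(drop=True)
    if len(a) != len(b):
        raise ValueError("label vectors differ in length")
    keep = a.notna() & b.notna()
    a, b = a[keep], b[keep]
    if a.empty:
        raise ValueError("no complete label pairs")
    table = pd.crosstab(a, b)
    cats = sorted(set(table.index) | set(table.columns))
    table = table.reindex(index=cats, columns=cats, fill_value=0)
    n = table.to_numpy().sum()
    p_o = np.trace(table.to_numpy()) / n
    p_e = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if p_e == 1.0:
        logger.warning("both raters constant and identical: kappa = 1 by convention")
        return 1.0
    return float((p_o - p_e) / (1 - p_e))


@dataclass
class MannWhitneyResult:
    p: float
    u: float
    mode: str       # "exact" | "approximate"


def mann_whitney(x, y, switchover: int = EXACT_SWITCHOVER) -> MannWhitneyResult:
    """Two-tailed Mann-Whitney test.

    Exact enumeration null when the combined sample size is at most
    ``switchover`` and there are no ties; normal approximation with tie
    correction otherwise. Empty groups are an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("Mann-Whitney requires two nonempty groups")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < pooled.size
    if x.size + y.size <= switchover and not ties:
        mode = "exact"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        mode = "approximate"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(p=float(min(res.pvalue, 1.0)), u=float(res.statistic),
                             mode=mode)


def group_comparisons(
    scores: pd.DataFrame,
    groups: pd.Series,
    group_order: list[str] | None = None,
    min_n: int = 1,
) -> dict[str, pd.DataFrame]:
    """All pairwise two-tailed Mann-Whitney p-values per score column.

    Returns, per score, an upper-triangular group x group frame of
    p-values; cells where a group has no applicable value are NaN.
    """
    groups = groups.reindex(scores.index)
    order = group_order or [g for g in pd.unique(groups.dropna())]
    out: dict[str, pd.DataFrame] = {}
    for col in scores.columns:
        mat = pd.DataFrame(np.nan, index=order, columns=order)
        for i, ga in enumerate(order):
            for gb in order[i + 1:]:
                xa = scores.loc[groups == ga, col].dropna()
                xb = scores.loc[groups == gb, col].dropna()
                if len(xa) < min_n or len(xb) < min_n:
                    continue
                mat.loc[ga, gb] = mann_whitney(xa, xb).p
        out[col] = mat
    return out


def per_gene_comparison(
    expr_values: pd.DataFrame,
    groups: pd.Series,
    pair: tuple[str, str],
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-gene two-group Mann-Whitney comparison, sorted by p.

    ``expr_values`` is genes x samples. Genes constant in both groups get
    p = 1 and a flag. ``adjust="bh"`` adds Benjamini-Hochberg q-values
    (off by default; the reproduced analysis reports unadjusted p)."""
    ga, gb = pair
    a_ids = groups.index[groups == ga]
    b_ids = groups.index[groups == gb]
    a_ids = [s for s in a_ids if s in expr_values.columns]
    b_ids = [s for s in b_ids if s in expr_values.columns]
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError(f"both groups need >= 2 samples ({ga}: {len(a_ids)}, "
                         f"{gb}: {len(b_ids)})")
    rows = []
    for gene in expr_values.index:
        xa = expr_values.loc[gene, a_ids].to_numpy(dtype=float)
        xb = expr_values.loc[gene, b_ids].to_numpy(dtype=float)
        if np.unique(np.concatenate([xa, xb])).size == 1:
            rows.append((gene, 1.0, "constant", np.median(xb) - np.median(xa)))
            continue
        res = mann_whitney(xa, xb)
        rows.append((gene, res.p, res.mode, float(np.median(xb) - np.median(xa))))
    out = pd.DataFrame(rows, columns=["gene", "p", "mode", "median_diff"])
    out = out.set_index("gene").sort_values("p", kind="stable")
    if adjust == "bh":
        out["q"] = sps.false_discovery_control(out["p"].to_numpy(), method="bh")
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out
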