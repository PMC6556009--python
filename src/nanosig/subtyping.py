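"""Intrinsic subtyping: nearest-centroid (PAM50-style) calls with a
dropout-stability check, and rule-based IHC surrogate subtypes.

The molecular call standardizes each gene across the cohort (robust mode:
median-centred, scaled by an inner-quantile range), computes rank
correlation to each of the five subtype centroids over shared genes and
takes the argmax. The IHC surrogate maps dichotomized ER/PR/HER2/Ki-67
markers through the published rule table; normal-like has no IHC
surrogate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ncounter import ExpressionMatrix
from .scoring import _centroid_correlations
from .signatures import SUBTYPES, CentroidSet

logger = logging.getLogger(__name__)

# fixed deterministic priority for (near-impossible) correlation ties
TIE_PRIORITY = ("basal", "Her2", "lumB", "lumA", "normal")

__all__ = [
    "IHCProfile",
    "dichotomize_markers",
    "ihc_surrogate",
    "robust_standardize",
    "pam50_classify",
    "subtype_stability",
    "discordance_rates",
    "ihc_calls",
    "dichotomized_status",
]


@dataclass
class IHCProfile:
    """Raw immunohistochemistry: ER/PR labelling percentages, HER2 staining
    category (0/1+/2+/3+, FISH-resolved, or missing) and Ki-67 labelling
    index (percent, or NaN)."""

    er_percent: float
    pr_percent: float
    her2: str = "missing"
    ki67_li: float = float("nan")

    def __post_init__(self) -> None:
        for v in (self.er_percent, self.pr_percent):
            if not np.isnan(v) and not 0 <= v <= 100:
                raise ValueError(f"percentage out of range: {v}")
        if not np.isnan(self.ki67_li) and not 0 <= self.ki67_li <= 100:
            raise ValueError(f"Ki-67 LI out of range: {self.ki67_li}")


_HER2_NEG = {"0", "1+", "FISH-"}
_HER2_POS = {"3+", "FISH+"}


def dichotomize_markers(p: IHCProfile):
    """ER/PR positive at >= 1% labelling; HER2 positive for 3+ or FISH+,
    negative for 0/1+/FISH-, and missing for unresolved 2+; Ki-67 high at
    LI >= 14%. Missing inputs propagate as None."""
    er = None if np.isnan(p.er_percent) else ("+" if p.er_percent >= 1 else "-")
    pr = None if np.isnan(p.pr_percent) else ("+" if p.pr_percent >= 1 else "-")
    if p.her2 in _HER2_POS:
        her2 = "+"
    elif p.her2 in _HER2_NEG:
        her2 = "-"
    else:   # unresolved 2+ or missing
        her2 = None
    ki67 = None if np.isnan(p.ki67_li) else ("high" if p.ki67_li >= 14 else "low")
    return er, pr, her2, ki67


def ihc_surrogate(p: IHCProfile) -> str:
    """IHC surrogate intrinsic subtype.

    lumA:  (ER+ and/or PR+), HER2-, Ki-67 low
    lumB:  (ER+ and/or PR+), HER2-, Ki-67 high; or (ER+ and/or PR+), HER2+
    Her2:  ER-, PR-, HER2+
    basal: ER-, PR-, HER2-

    Any marker needed by the applicable rule that is missing yields
    ``"unknown"``; normal-like is never assigned.
    """
    er, pr, her2, ki67 = dichotomize_markers(p)
    if er is None or pr is None or her2 is None:
        return "unknown"
    hr_pos = er == "+" or pr == "+"
    if hr_pos:
        if her2 == "+":
            return "lumB"
        if ki67 is None:
            return "unknown"
        return "lumA" if ki67 == "low" else "lumB"
    return "Her2" if her2 == "+" else "basal"


def ihc_calls(annotations: pd.DataFrame) -> pd.Series:
    """Apply the surrogate rules to an annotation table with columns
    er_percent, pr_percent, her2, ki67_li."""
    out = {}
    for sid, row in annotations.iterrows():
        out[sid] = ihc_surrogate(
            IHCProfile(
                er_percent=float(row["er_percent"]),
                pr_percent=float(row["pr_percent"]),
                her2=str(row["her2"]),
                ki67_li=float(row["ki67_li"]) if pd.notna(row["ki67_li"]) else float("nan"),
            )
        )
    return pd.Series(out, name="ihc").rename_axis("sample_id")


def dichotomized_status(annotations: pd.DataFrame) -> pd.DataFrame:
    """Boolean er_pos/pr_pos/her2_pos/ki67_high per sample (pd.NA where
    missing) — the applicability input for RS/EP."""
    recs = {}
    for sid, row in annotations.iterrows():
        er, pr, her2, ki67 = dichotomize_markers(
            IHCProfile(
                er_percent=float(row["er_percent"]),
                pr_percent=float(row["pr_percent"]),
                her2=str(row["her2"]),
                ki67_li=float(row["ki67_li"]) if pd.notna(row["ki67_li"]) else float("nan"),
            )
        )
        recs[sid] = {
            "er_pos": pd.NA if er is None else er == "+",
            "pr_pos": pd.NA if pr is None else pr == "+",
            "her2_pos": pd.NA if her2 is None else her2 == "+",
            "ki67_high": pd.NA if ki67 is None else ki67 == "high",
        }
    return pd.DataFrame.from_dict(recs, orient="index").rename_axis("sample_id")


def robust_standardize(
    expr: ExpressionMatrix, mode: str = "robust", q: float = 0.05
) -> ExpressionMatrix:
    """Per-gene standardization across the cohort.

    robust: median-centre, scale by the (q, 1-q) inner-quantile range;
    zscore: mean-centre, scale by SD; none: passthrough. Genes with zero
    spread are centred only.
    """
    vals = expr.values
    if mode == "none":
        return expr
    if mode == "robust":
        centre = vals.median(axis=1)
        spread = vals.quantile(1 - q, axis=1) - vals.quantile(q, axis=1)
    elif mode == "zscore":
        centre = vals.mean(axis=1)
        spread = vals.std(axis=1)
    else:
        raise ValueError(f"unknown standardization mode {mode!r}")
    spread = spread.replace(0.0, 1.0).fillna(1.0)
    out = vals.sub(centre, axis=0).div(spread, axis=0)
    return replace(expr, values=out, steps=expr.steps + (f"standardize[{mode}]",))


def pam50_classify(
    expr: ExpressionMatrix,
    centroids: CentroidSet,
    standardization: str = "robust",
    method: str = "spearman",
    min_overlap: int = 30,
) -> pd.DataFrame:
    """Nearest-centroid subtype calls.

    Returns one row per sample: ``pam50`` call, and the correlation to each
    of the five centroids (columns ``corr_<subtype>``). Ties are broken by
    a fixed priority (basal > Her2 > lumB > lumA > normal) with a warning.
    """
    std = robust_standardize(expr, mode=standardization)
    corr = _centroid_correlations(std, centroids, method=method, min_overlap=min_overlap)
    prio = {s: i for i, s in enumerate(TIE_PRIORITY)}
    calls = []
    for sid, row in corr.iterrows():
        best = row.max()
        winners = [s for s in SUBTYPES if row[s] == best]
        if len(winners) > 1:
            logger.warning("tied centroid correlations for %s: %s", sid, winners)
            winners.sort(key=prio.__getitem__)
        calls.append(winners[0])
    out = corr.add_prefix("corr_")
    out.insert(0, "pam50", calls)
    out.index.name = "sample_id"
    return out


def subtype_stability(
    expr: ExpressionMatrix,
    centroids: CentroidSet,
    dropped_genes,
    **kwargs,
):
    """Classify with the full and the gene-depleted centroid set; report
    the fraction of samples whose call changes and their ids."""
    dropped = set(dropped_genes)
    stray = dropped - set(centroids.genes)
    if stray:
        raise ValueError(f"dropped genes not in centroid set: {sorted(stray)}")
    full = pam50_classify(expr, centroids, **kwargs)["pam50"]
    reduced = pam50_classify(expr, centroids.drop_genes(dropped), **kwargs)["pam50"]
    changed = full.index[full != reduced].tolist()
    return len(changed) / len(full), changed


def discordance_rates(calls: pd.DataFrame) -> pd.Series:
    """Per-subtype discordance between molecular and IHC calls.

    For each non-normal molecular subtype s: the fraction of samples called
    s by the classifier whose IHC surrogate differs. Normal-like molecular
    calls and unknown IHC calls are excluded; an empty class is NaN.
    """
    sub = calls[(calls["pam50"] != "normal") & (calls["ihc"] != "unknown")]
    if sub.empty:
        logger.warning("no comparable calls for discordance rates")
    rates = {}
    for s in SUBTYPES[1:]:
        grp = sub[sub["pam50"] == s]
        rates[s] = np.nan if grp.empty else float((grp["ihc"] != s).mean())
    return pd.Series(rates, name="discordance")
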