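"""Per-sample molecular scores and subscores.

Each score is ``intercept + sum_g group_weight_g * group_score_g`` on
log2 expression normalized against the signature's *own* reference genes.
Group scores are gene-weight-weighted means; genes absent from the panel
are dropped with a warning and the remaining weights renormalized (the
policy used for the two classifier genes missing from the CodeSet).

ROR-P is different in kind: a linear combination of the sample's
correlations to the five subtype centroids plus a proliferation term
(mean expression of the classifier's proliferation gene subset).

Samples failing a signature's applicability rule (RS and EP are defined
for ER+/HER2- tumours only, judged by IHC) carry NaN, not zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ncounter import CountMatrix, ExpressionMatrix, reference_normalize
from .signatures import SUBTYPES, CentroidSet, SignatureDefinition, SignatureGroup

logger = logging.getLogger(__name__)

SUBSCORE_NAMES = ("PRO", "ER", "PR", "HER2")

__all__ = [
    "group_score",
    "compute_score",
    "compute_ror_p",
    "compute_subscores",
    "score_table",
]


class ScoringError(ValueError):
    pass


def group_score(expr_sample: pd.Series, group: SignatureGroup) -> float:
    """Gene-weight-weighted mean of the group's member genes for one sample.

    Missing members are dropped and the weights renormalized; a group with
    no measured member is an error.
    """
    present = [(g, w) for g, w in group.members if g in expr_sample.index]
    if not present:
        raise ScoringError(f"all member genes of group {group.name!r} are missing")
    if len(present) < len(group.members):
        dropped = [g for g, _ in group.members if g not in expr_sample.index]
        logger.warning("group %s: dropping unmeasured gene(s) %s", group.name, dropped)
    genes = [g for g, _ in present]
    w = np.array([w for _, w in present], dtype=float)
    return float(np.dot(expr_sample[genes].to_numpy(), w) / w.sum())


def _group_scores_frame(expr: ExpressionMatrix, sig: SignatureDefinition) -> pd.DataFrame:
    """All group scores, groups x samples (vectorized over samples)."""
    vals = expr.values
    out = {}
    for idx, grp in enumerate(sig.groups):
        present = [(g, w) for g, w in grp.members if g in vals.index]
        if not present:
            raise ScoringError(
                f"signature {sig.name}: all member genes of group {grp.name!r} missing"
            )
        if len(present) < len(grp.members):
            dropped = [g for g, _ in grp.members if g not in vals.index]
            logger.warning(
                "%s group %s: dropping unmeasured gene(s) %s", sig.name, grp.name, dropped
            )
        genes = [g for g, _ in present]
        w = np.array([w for _, w in present], dtype=float)
        out[idx] = vals.loc[genes].mul(w, axis=0).sum(axis=0) / w.sum()
    return pd.DataFrame(out).T


def applicability_mask(sig: SignatureDefinition, ihc_status: pd.DataFrame | None,
                       samples) -> pd.Series:
    """True where the signature applies. ``ihc_status`` needs boolean-ish
    columns ``er_pos`` and ``her2_pos`` (NaN = unknown -> not applicable)."""
    samples = pd.Index(samples)
    if sig.applicability == "all":
        return pd.Series(True, index=samples)
    if ihc_status is None:
        logger.warning("%s requires IHC status but none given: all not-applicable",
                       sig.name)
        return pd.Series(False, index=samples)
    st = ihc_status.reindex(samples)
    ok = (st["er_pos"] == True) & (st["her2_pos"] == False)  # noqa: E712 (NaN-safe)
    return ok.fillna(False).astype(bool)


def compute_score(
    expr: ExpressionMatrix,
    sig: SignatureDefinition,
    ihc_status: pd.DataFrame | None = None,
) -> pd.Series:
    """The signature's score per sample (NaN where not applicable).

    ``expr`` must be normalized against the signature's own reference
    genes; no clipping, thresholding or rescaling is applied.
    """
    gs = _group_scores_frame(expr, sig)
    weights = np.array([g.weight for g in sig.groups])
    score = sig.intercept + gs.mul(weights, axis=0).sum(axis=0)
    mask = applicability_mask(sig, ihc_status, expr.samples)
    return score.where(mask).rename(sig.name)


def _centroid_correlations(
    expr: ExpressionMatrix,
    centroids: CentroidSet,
    method: str = "spearman",
    min_overlap: int = 30,
) -> pd.DataFrame:
    shared = [g for g in centroids.genes if g in expr.values.index]
    if len(shared) < min_overlap:
        raise ScoringError(
            f"only {len(shared)} genes shared with the centroid set "
            f"(minimum {min_overlap})"
        )
    if len(shared) < len(centroids.genes):
        logger.warning(
            "centroid correlation on %d of %d genes (unmeasured dropped)",
            len(shared), len(centroids.genes),
        )
    x = expr.values.loc[shared].to_numpy()
    c = centroids.centroids.loc[shared].to_numpy()
    if method == "spearman":
        x = sps.rankdata(x, axis=0)
        c = sps.rankdata(c, axis=0)
    elif method != "pearson":
        raise ScoringError(f"unknown correlation method {method!r}")
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    c = (c - c.mean(axis=0)) / c.std(axis=0)
    corr = x.T @ c / x.shape[0]
    return pd.DataFrame(corr, index=expr.samples, columns=list(SUBTYPES))


def compute_ror_p(
    expr: ExpressionMatrix,
    centroids: CentroidSet,
    method: str = "spearman",
    min_overlap: int = 30,
) -> pd.Series:
    """ROR-P: intercept + sum_k coef_k * corr(sample, centroid_k)
    + pro_coefficient * mean expression of the proliferation subset."""
    corr = _centroid_correlations(expr, centroids, method, min_overlap)
    coef = pd.Series(
        {s: centroids.ror_coefficients.get(s, 0.0) for s in SUBTYPES}, dtype=float
    )
    score = centroids.ror_intercept + corr.mul(coef, axis=1).sum(axis=1)
    if centroids.ror_pro_coefficient != 0.0:
        score = score + centroids.ror_pro_coefficient * proliferation_subscore(
            expr, centroids
        )
    return score.rename("ROR-P")


def proliferation_subscore(expr: ExpressionMatrix, centroids: CentroidSet) -> pd.Series:
    """Mean expression of the classifier's proliferation genes (measured
    subset; unmeasured members dropped with a warning)."""
    present = [g for g in centroids.proliferation_genes if g in expr.values.index]
    if not present:
        raise ScoringError("no proliferation gene measured")
    missing = set(centroids.proliferation_genes) - set(present)
    if missing:
        logger.warning("proliferation subscore: dropping %s", sorted(missing))
    return expr.values.loc[present].mean(axis=0).rename("ROR-P_PRO")


def compute_subscores(
    expr: ExpressionMatrix, sig: SignatureDefinition
) -> pd.DataFrame:
    """Group scores of the PRO/ER/PR/HER2-tagged groups, one column per
    available tag, named ``<signature>_<tag>``. Tags the signature lacks
    are simply absent from the result."""
    gs = _group_scores_frame(expr, sig)
    cols = {}
    for idx, grp in enumerate(sig.groups):
        if grp.name in SUBSCORE_NAMES and f"{sig.name}_{grp.name}" not in cols:
            cols[f"{sig.name}_{grp.name}"] = gs.loc[idx]
    return pd.DataFrame(cols)


def score_table(
    counts: CountMatrix,
    signatures: dict[str, SignatureDefinition],
    centroids: CentroidSet,
    ihc_status: pd.DataFrame | None = None,
    pam50_reference_genes=None,
    correlation: str = "spearman",
) -> pd.DataFrame:
    """Scores and subscores for a background-corrected, positive-control
    scaled count matrix.

    Implements per-score normalization: every signature is evaluated on
    expression normalized against its own reference genes; ROR-P and its
    PRO-subscore use expression normalized with the classifier reference
    genes (``pam50_reference_genes``).
    """
    cols = []
    for sig in signatures.values():
        expr = reference_normalize(counts, sig.reference_genes)
        cols.append(compute_score(expr, sig, ihc_status))
        sub = compute_subscores(expr, sig)
        mask = applicability_mask(sig, ihc_status, expr.samples)
        cols.append(sub.where(mask, axis=0))
    if pam50_reference_genes is not None:
        pexpr = reference_normalize(counts, pam50_reference_genes)
        cols.append(compute_ror_p(pexpr, centroids, method=correlation))
        cols.append(proliferation_subscore(pexpr, centroids))
    out = pd.concat(cols, axis=1)
    out.index.name = "sample_id"
    return out
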