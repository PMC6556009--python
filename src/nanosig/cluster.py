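"""Hierarchical clustering of samples and matched-pair proximity.

Samples are clustered agglomeratively on Euclidean distance over a
restricted gene set (the union of the signatures' test genes). Matched
primary/recurrence pairs are then scored by how close they sit in the
dendrogram leaf order; a permutation null formalizes "pairs cluster in
the immediate vicinity of each other".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .ncounter import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterResult",
    "PairProximity",
    "hierarchical_cluster",
    "pair_proximity",
    "pair_proximity_null",
]


@dataclass
class ClusterResult:
    linkage: np.ndarray            # scipy linkage matrix
    samples: list[str]             # observation order fed to linkage
    leaf_order: list[str]          # dendrogram left-to-right sample order
    metric: str
    method: str
    genes: list[str] = field(default_factory=list)

    @property
    def leaf_positions(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.leaf_order)}


@dataclass
class PairProximity:
    table: pd.DataFrame            # per pair: members, leaf distance, cophenetic rank
    window: int
    n_in_vicinity: int
    skipped: list[str] = field(default_factory=list)


def hierarchical_cluster(
    expr: ExpressionMatrix,
    genes=None,
    method: str = "average",
    metric: str = "euclidean",
) -> ClusterResult:
    """Agglomerative clustering of samples over ``genes`` (default: all).

    Deterministic given sample order; scipy's tie handling is stable in
    input index order.
    """
    genes = list(genes) if genes is not None else list(expr.values.index)
    if not genes:
        raise ValueError("empty gene set for clustering")
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise ValueError(f"gene(s) not in expression matrix: {missing}")
    if len(expr.samples) < 2:
        raise ValueError("clustering needs >= 2 samples")
    x = expr.values.loc[genes].T.to_numpy()
    z = hierarchy.linkage(x, method=method, metric=metric)
    order = hierarchy.leaves_list(z)
    samples = list(expr.samples)
    return ClusterResult(
        linkage=z,
        samples=samples,
        leaf_order=[samples[i] for i in order],
        metric=metric,
        method=method,
        genes=genes,
    )


def _cophenetic_ranks(result: ClusterResult) -> pd.DataFrame:
    coph = squareform(hierarchy.cophenet(result.linkage))
    return pd.DataFrame(coph, index=result.samples, columns=result.samples)


def pair_proximity(
    result: ClusterResult,
    pairs: list[tuple[str, str]],
    window: int = 2,
) -> PairProximity:
    """Leaf-order distance and cophenetic rank per matched pair.

    A pair is "in vicinity" when the absolute difference of its members'
    leaf positions is at most ``window``. The cophenetic rank counts the
    other samples already merged below the pair's own merge height (the
    size of the smallest cluster containing both, minus the pair itself).
    Pairs with an absent member are skipped with a warning.
    """
    pos = result.leaf_positions
    coph = _cophenetic_ranks(result)
    rows, skipped = [], []
    for a, b in pairs:
        if a not in pos or b not in pos:
            logger.warning("pair (%s, %s): member missing from clustering", a, b)
            skipped.append(f"{a}|{b}")
            continue
        dist = abs(pos[a] - pos[b])
        h = coph.loc[a, b]
        rank = int((coph.loc[a] <= h).sum() - 2)  # others joining at/below pair height
        rows.append((a, b, dist, dist <= window, rank))
    table = pd.DataFrame(
        rows,
        columns=["sample_a", "sample_b", "leaf_distance", "in_vicinity",
                 "cophenetic_rank"],
    )
    return PairProximity(
        table=table,
        window=window,
        n_in_vicinity=int(table["in_vicinity"].sum()) if len(table) else 0,
        skipped=skipped,
    )


def _vicinity_count(positions: np.ndarray, pair_idx: np.ndarray, window: int) -> int:
    d = np.abs(positions[pair_idx[:, 0]] - positions[pair_idx[:, 1]])
    return int((d <= window).sum())


def pair_proximity_null(
    result: ClusterResult,
    pairs: list[tuple[str, str]],
    window: int = 2,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """Permutation p-value for the observed vicinity count.

    Sample positions on the leaf order are permuted ``n_perm`` times; the
    p-value is the add-one-smoothed fraction of permutations whose count
    reaches the observed one.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    pos = result.leaf_positions
    usable = [(a, b) for a, b in pairs if a in pos and b in pos]
    obs = pair_proximity(result, usable, window).n_in_vicinity
    idx = {s: i for i, s in enumerate(result.samples)}
    pair_idx = np.array([[idx[a], idx[b]] for a, b in usable], dtype=int)
    n = len(result.samples)
    rng = np.random.default_rng(seed)
    ge = 0
    base = np.empty(n, dtype=int)
    for _ in range(n_perm):
        base[rng.permutation(n)] = np.arange(n)
        if len(pair_idx) and _vicinity_count(base, pair_idx, window) >= obs:
            ge += 1
    if not len(pair_idx):
        ge = n_perm
    return {
        "observed": obs,
        "n_pairs": len(usable),
        "window": window,
        "n_perm": n_perm,
        "p": (ge + 1) / (n_perm + 1),
    }
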