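"""Reading and normalizing nCounter-style count tables.

The nCounter platform reports digital hybridization counts for four probe
classes: endogenous test probes, stably expressed reference (housekeeping)
probes, negative controls (probes with no target, estimating background)
and positive controls (spike-in RNAs at fixed concentrations, estimating
per-lane hybridization efficiency).

The normalization chain implemented here follows the conventional order

    background correction -> positive-control scaling
    -> reference-gene normalization -> log2,

where background is subtracted per sample from the mean of the negative
controls, positive-control scaling equalizes each sample's positive-probe
geometric mean to the cohort grand geometric mean, and reference-gene
normalization expresses each gene as log2 count minus the sample's mean
log2 reference-gene count (so reference genes average exactly zero in
every sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

PROBE_CLASSES = ("endogenous", "reference", "negative", "positive")

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "QCReport",
    "QCThresholds",
    "read_counts",
    "write_counts",
    "background_correct",
    "positive_control_scale",
    "reference_normalize",
    "qc_filter",
]


class NCounterError(ValueError):
    """Raised on malformed count tables or impossible normalization requests."""


@dataclass
class CountMatrix:
    """Raw or partially normalized counts, probes x samples.

    ``probes`` carries one row per probe with columns ``gene_symbol`` and
    ``probe_class`` and the probe id as index; ``counts`` is a float frame
    aligned to it (raw input is integer, background correction and scaling
    produce floats).
    """

    probes: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.probes.index.is_unique:
            dup = self.probes.index[self.probes.index.duplicated()].unique().tolist()
            raise NCounterError(f"duplicate probe_id(s): {dup}")
        if not self.counts.columns.is_unique:
            raise NCounterError("duplicate sample ids")
        unknown = set(self.probes["probe_class"]) - set(PROBE_CLASSES)
        if unknown:
            raise NCounterError(f"unknown probe class(es): {sorted(unknown)}")
        if not self.counts.index.equals(self.probes.index):
            raise NCounterError("counts and probe annotation are not aligned")
        if (self.counts.to_numpy() < 0).any():
            raise NCounterError("negative counts")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def class_index(self, probe_class: str) -> pd.Index:
        return self.probes.index[self.probes["probe_class"] == probe_class]

    def class_counts(self, probe_class: str) -> pd.DataFrame:
        return self.counts.loc[self.class_index(probe_class)]

    def subset_samples(self, samples: list[str]) -> "CountMatrix":
        return CountMatrix(self.probes, self.counts[samples])


@dataclass
class ExpressionMatrix:
    """log2 normalized expression, genes x samples, plus provenance."""

    values: pd.DataFrame            # index: gene_symbol
    reference_genes: tuple[str, ...]
    steps: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise NCounterError("non-finite normalized expression")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class QCThresholds:
    """Sample QC rules: minimum total (endogenous+reference) counts and
    minimum fraction of endogenous probes above the sample's background."""

    min_total_counts: float = 2000.0
    min_frac_above_background: float = 0.5


@dataclass
class QCReport:
    metrics: pd.DataFrame           # per sample: total_counts, pos_geomean, frac_above_background
    passed: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)
    reasons: dict[str, str] = field(default_factory=dict)


def read_counts(path, sep: str = "\t") -> CountMatrix:
    """Read a delimited count table.

    Expected layout: columns ``probe_id``, ``gene_symbol``, ``probe_class``
    followed by one integer column per sample.
    """
    df = pd.read_csv(path, sep=sep, dtype={"probe_id": str, "gene_symbol": str})
    required = ["probe_id", "gene_symbol", "probe_class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise NCounterError(f"count table lacks column(s) {missing}")
    sample_cols = [c for c in df.columns if c not in required]
    if not sample_cols:
        raise NCounterError("count table has no sample columns")
    for col in sample_cols:
        vals = df[col]
        numeric = pd.to_numeric(vals, errors="coerce")
        bad = numeric.isna() | (numeric < 0) | (numeric != numeric.round())
        if bad.any():
            row = df.loc[bad.idxmax(), "probe_id"]
            raise NCounterError(
                f"non-integer or negative count at probe {row!r}, sample {col!r}"
            )
        df[col] = numeric.astype(float)
    probes = df[required].set_index("probe_id")
    counts = df.set_index("probe_id")[sample_cols]
    return CountMatrix(probes=probes, counts=counts)


def write_counts(cm: CountMatrix, path, sep: str = "\t") -> None:
    out = pd.concat([cm.probes, cm.counts], axis=1)
    out.index.name = "probe_id"
    out.to_csv(path, sep=sep)


def _background(cm: CountMatrix, method: str) -> pd.Series:
    neg = cm.class_counts("negative")
    if neg.empty:
        raise NCounterError("background correction impossible: no negative-control probes")
    if method == "mean":
        return neg.mean(axis=0)
    if method == "mean2sd":
        return neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1).fillna(0.0)
    if method == "max":
        return neg.max(axis=0)
    raise NCounterError(f"unknown background method {method!r}")


def background_correct(cm: CountMatrix, method: str = "mean", floor: float = 1.0) -> CountMatrix:
    """Subtract per-sample background from endogenous and reference counts.

    Background defaults to the mean of the negative controls; corrected
    counts are floored at 1 so later log transforms stay finite. Negative
    controls are retained untouched for QC reporting.
    """
    bg = _background(cm, method)
    counts = cm.counts.copy()
    target = cm.probes["probe_class"].isin(["endogenous", "reference"]).to_numpy()
    corrected = counts.loc[target].sub(bg, axis=1).clip(lower=floor)
    counts.loc[target] = corrected
    return CountMatrix(cm.probes, counts)


def positive_control_scale(cm: CountMatrix) -> CountMatrix:
    """Scale each sample so its positive-control geometric mean matches the
    cohort grand geometric mean. All non-negative-control counts are scaled;
    a sample whose positive controls are all zero cannot be scaled and is a
    QC failure."""
    pos = cm.class_counts("positive")
    if len(pos) < 2:
        raise NCounterError("positive-control scaling needs >= 2 positive probes")
    dead = (pos <= 0).all(axis=0)
    if dead.any():
        raise NCounterError(
            f"sample(s) with all-zero positive controls: {list(pos.columns[dead])}"
        )
    # geometric means on floored counts, avoiding log(0)
    logpos = np.log(pos.clip(lower=1.0))
    sample_geomean = np.exp(logpos.mean(axis=0))
    grand = float(np.exp(np.log(sample_geomean).mean()))
    factors = grand / sample_geomean
    counts = cm.counts.copy()
    target = (cm.probes["probe_class"] != "negative").to_numpy()
    counts.loc[target] = counts.loc[target].mul(factors, axis=1)
    return CountMatrix(cm.probes, counts)


def reference_normalize(cm: CountMatrix, ref_genes) -> ExpressionMatrix:
    """Reference-gene normalization: log2(count) minus the per-sample mean
    log2 count of ``ref_genes``. Returns endogenous + reference probes,
    indexed by gene symbol."""
    ref_genes = sorted(set(ref_genes))
    keep = cm.probes["probe_class"].isin(["endogenous", "reference"])
    sub = cm.counts.loc[keep.to_numpy()]
    symbols = cm.probes.loc[keep, "gene_symbol"]
    absent = [g for g in ref_genes if g not in set(symbols)]
    if absent:
        raise NCounterError(f"reference gene(s) absent from panel: {absent}")
    if (sub.to_numpy() <= 0).any():
        raise NCounterError("non-positive counts; background-correct (floor>=1) first")
    log2 = np.log2(sub.set_axis(symbols.to_numpy(), axis=0))
    ref_mean = log2.loc[ref_genes].mean(axis=0)
    values = log2.sub(ref_mean, axis=1)
    return ExpressionMatrix(
        values=values,
        reference_genes=tuple(ref_genes),
        steps=("log2", f"reference_normalize[{len(ref_genes)} genes]"),
    )


def qc_filter(cm: CountMatrix, thresholds: QCThresholds | None = None):
    """Flag and drop poor-quality samples.

    Criteria: total endogenous+reference counts below ``min_total_counts``,
    or fraction of endogenous probes above the sample's mean negative-control
    background below ``min_frac_above_background``.
    """
    thresholds = thresholds or QCThresholds()
    endo_ref = cm.probes["probe_class"].isin(["endogenous", "reference"]).to_numpy()
    total = cm.counts.loc[endo_ref].sum(axis=0)
    neg = cm.class_counts("negative")
    bg = neg.mean(axis=0) if len(neg) else pd.Series(0.0, index=cm.counts.columns)
    endo = cm.class_counts("endogenous")
    frac_above = (endo.gt(bg, axis=1)).mean(axis=0) if len(endo) else pd.Series(
        1.0, index=cm.counts.columns
    )
    pos = cm.class_counts("positive")
    pos_geomean = (
        np.exp(np.log(pos.clip(lower=1.0)).mean(axis=0))
        if len(pos)
        else pd.Series(np.nan, index=cm.counts.columns)
    )
    metrics = pd.DataFrame(
        {
            "total_counts": total,
            "pos_geomean": pos_geomean,
            "frac_above_background": frac_above,
        }
    )
    reasons: dict[str, str] = {}
    for s in cm.samples:
        if total[s] < thresholds.min_total_counts:
            reasons[s] = "total counts"
        elif frac_above[s] < thresholds.min_frac_above_background:
            reasons[s] = "fraction above background"
    passed = [s for s in cm.samples if s not in reasons]
    if not passed:
        raise NCounterError("QC thresholds exclude every sample (empty cohort)")
    report = QCReport(
        metrics=metrics, passed=passed, excluded=list(reasons), reasons=reasons
    )
    return cm.subset_samples(passed), report


def normalize(
    cm: CountMatrix,
    ref_genes,
    background_method: str = "mean",
) -> ExpressionMatrix:
    """Full chain on a QC-passed matrix: background -> positive-control
    scaling -> reference normalization -> log2."""
    cm = background_correct(cm, method=background_method)
    cm = positive_control_scale(cm)
    expr = reference_normalize(cm, ref_genes)
    return replace(
        expr,
        steps=(f"background[{background_method}]", "positive_control_scale") + expr.steps,
    )
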