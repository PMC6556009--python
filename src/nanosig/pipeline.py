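"""End-to-end orchestration: QC/normalize -> score -> subtype ->
concordance -> group statistics -> clustering, from a single run config,
with a machine-readable manifest and seed-deterministic outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, cluster, ncounter, scoring, stats, subtyping
from .signatures import (
    combined_reference_genes,
    load_packaged_centroids,
    load_packaged_panel,
    load_packaged_signatures,
    union_test_genes,
)
from .simulate import GROUPS, GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "summarize_cohort", "extract_pairs"]


@dataclass
class RunConfig:
    """Exactly one of ``counts_path`` or ``generator`` must be supplied."""

    outdir: str = "results/run"
    counts_path: str | None = None
    annotations_path: str | None = None
    generator: GeneratorConfig | None = None
    seed: int = 0
    background_method: str = "mean"
    standardization: str = "robust"
    correlation: str = "spearman"
    linkage: str = "average"
    vicinity_window: int = 2
    n_perm: int = 2000
    qc: ncounter.QCThresholds = field(default_factory=ncounter.QCThresholds)

    def validate(self) -> None:
        if (self.counts_path is None) == (self.generator is None):
            raise ValueError("supply exactly one of counts_path or generator config")


def _manifest_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, manifest_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# manifest: {manifest_hash}\n")
        df.to_csv(fh, sep="\t")


def extract_pairs(annotations: pd.DataFrame) -> dict[str, list[tuple[str, str]]]:
    """Matched pairs by pair-id prefix: LP* local, BP* brain."""
    pairs: dict[str, list[tuple[str, str]]] = {"local": [], "brain": []}
    ann = annotations[annotations["pair_id"].astype(str).str.len() > 0]
    for pid, sub in ann.groupby("pair_id"):
        if len(sub) == 2:
            kind = "local" if str(pid).startswith("L") else "brain"
            pairs[kind].append(tuple(sub.index))
    return pairs


def summarize_cohort(annotations: pd.DataFrame, calls: pd.DataFrame | None = None
                     ) -> pd.DataFrame:
    """Cohort characteristics per clinical group: dichotomized IHC markers
    and subtype calls, as count (percent) strings."""
    status = subtyping.dichotomized_status(annotations)
    ihc = subtyping.ihc_calls(annotations)
    groups = annotations["group"]
    order = [g for g in GROUPS if g in set(groups)] or sorted(set(groups))
    rows: dict[str, dict[str, str]] = {}

    def add(row_name: str, mask: pd.Series) -> None:
        rows[row_name] = {}
        for g in order:
            in_g = groups == g
            n = int((mask & in_g).sum())
            tot = int(in_g.sum())
            rows[row_name][g] = f"{n} ({0 if not tot else round(100 * n / tot)}%)"

    for marker, label in [("er_pos", "ER+"), ("pr_pos", "PR+"), ("her2_pos", "Her2+"),
                          ("ki67_high", "Ki-67 high")]:
        add(label, status[marker].astype("boolean").fillna(False).astype(bool))
        add(f"{label.split('+')[0].split(' ')[0]} missing", status[marker].isna())
    for s in ["lumA", "lumB", "Her2", "basal", "unknown"]:
        add(f"IHC {s}", ihc == s)
    if calls is not None:
        pam = calls["pam50"].reindex(annotations.index)
        for s in ["normal", "lumA", "lumB", "Her2", "basal"]:
            add(f"PAM50 {s}", pam == s)
    out = pd.DataFrame(rows).T[order]
    out.index.name = "characteristic"
    return out


def run_pipeline(cfg: RunConfig) -> dict[str, object]:
    """Run the full analysis; returns in-memory results and writes TSVs plus
    a JSON manifest under ``cfg.outdir``."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    class _Capture(logging.Handler):
        def emit(self, record: logging.LogRecord) -> None:
            if record.levelno >= logging.WARNING:
                warnings.append(record.getMessage())

    capture = _Capture()
    logging.getLogger("nanosig").addHandler(capture)
    try:
        return _run(cfg, outdir, warnings)
    finally:
        logging.getLogger("nanosig").removeHandler(capture)


def _run(cfg: RunConfig, outdir: Path, warnings: list[str]) -> dict[str, object]:
    signatures = load_packaged_signatures()
    centroids = load_packaged_centroids()
    panel = load_packaged_panel()

    if cfg.generator is not None:
        gen = cfg.generator
        counts, annotations, truth = generate_cohort(gen)
    else:
        counts = ncounter.read_counts(cfg.counts_path)
        truth = None
        annotations = (
            pd.read_csv(cfg.annotations_path, sep="\t", index_col="sample_id")
            if cfg.annotations_path
            else None
        )

    manifest: dict = {
        "package": "nanosig",
        "version": __version__,
        "seed": cfg.seed,
        "options": {
            k: v
            for k, v in asdict(cfg).items()
            if k not in ("generator",)
        },
        "generator": None if cfg.generator is None else asdict(cfg.generator),
    }
    # the hash identifies the analysis, not where it is written
    hashed = dict(manifest, options={k: v for k, v in manifest["options"].items()
                                     if k != "outdir"})
    mhash = _manifest_hash(hashed)
    manifest["hash"] = mhash

    # --- QC + normalization with the combined reference-gene set
    counts_qc, qc_report = ncounter.qc_filter(counts, cfg.qc)
    for s in qc_report.excluded:
        logger.warning("QC excluded sample %s (%s)", s, qc_report.reasons[s])
    all_sigs = list(signatures.values()) + [centroids]
    refs = combined_reference_genes(all_sigs)
    expr = ncounter.normalize(counts_qc, refs, background_method=cfg.background_method)
    if annotations is not None:
        annotations = annotations.loc[[s for s in expr.samples if s in annotations.index]]

    # --- scores (per-score normalization inside) and subtypes
    scaled = ncounter.positive_control_scale(
        ncounter.background_correct(counts_qc, method=cfg.background_method)
    )
    ihc_status = (
        subtyping.dichotomized_status(annotations) if annotations is not None else None
    )
    scores = scoring.score_table(
        scaled,
        signatures,
        centroids,
        ihc_status=ihc_status,
        pam50_reference_genes=centroids.reference_genes,
        correlation=cfg.correlation,
    )
    pam_expr = ncounter.reference_normalize(scaled, centroids.reference_genes)
    calls = subtyping.pam50_classify(
        pam_expr, centroids, standardization=cfg.standardization, method=cfg.correlation
    )
    if annotations is not None:
        calls["ihc"] = subtyping.ihc_calls(annotations)
        discord = subtyping.discordance_rates(calls)
        cmp_mask = (calls["pam50"] != "normal") & (calls["ihc"] != "unknown")
        kappa_ihc = stats.cohens_kappa(
            calls.loc[cmp_mask, "pam50"], calls.loc[cmp_mask, "ihc"]
        )
    else:
        discord, kappa_ihc = None, None

    # --- concordance between scores
    score_cols = [c for c in ["RISK", "RS", "ROR-P", "EP"] if c in scores.columns]
    primaries = (
        annotations.index[
            annotations["group"].isin(["control", "primary_local", "primary_distant"])
        ]
        if annotations is not None
        else scores.index
    )
    prim_scores = scores.loc[[s for s in primaries if s in scores.index]]
    rho, rho_n = stats.spearman_matrix(prim_scores[score_cols])
    kappa = pd.DataFrame(1.0, index=score_cols, columns=score_cols)
    for i, a in enumerate(score_cols):
        for b in score_cols[i + 1:]:
            sub = prim_scores[[a, b]].dropna()
            if len(sub) < 3:
                kappa.loc[a, b] = kappa.loc[b, a] = float("nan")
                continue
            ka = stats.tertile_dichotomize(sub[a])
            kb = stats.tertile_dichotomize(sub[b])
            kappa.loc[a, b] = kappa.loc[b, a] = stats.cohens_kappa(ka, kb)

    sub_cols = [c for c in scores.columns if c not in score_cols]
    rho_sub, _ = stats.spearman_matrix(prim_scores[sub_cols]) if sub_cols else (None, None)

    # --- group and subtype comparisons
    results: dict[str, object] = {}
    if annotations is not None:
        group_p = stats.group_comparisons(
            scores, annotations["group"], group_order=list(GROUPS)
        )
        prim_groups = annotations.loc[prim_scores.index, "group"]
        subtype_p = stats.group_comparisons(
            prim_scores[score_cols],
            calls.loc[prim_scores.index, "pam50"],
            group_order=["normal", "lumA", "lumB", "Her2", "basal"],
        )
    else:
        group_p, subtype_p = None, None

    # --- clustering over the signature-gene union + matched-pair proximity
    union = union_test_genes(all_sigs, panel)
    clust = cluster.hierarchical_cluster(expr, genes=union, method=cfg.linkage)
    if annotations is not None and "pair_id" in annotations.columns:
        pairs = extract_pairs(annotations)
        proximity = {
            kind: cluster.pair_proximity(clust, plist, window=cfg.vicinity_window)
            for kind, plist in pairs.items()
        }
        proximity_null = {
            kind: cluster.pair_proximity_null(
                clust, plist, window=cfg.vicinity_window,
                n_perm=cfg.n_perm, seed=cfg.seed,
            )
            for kind, plist in pairs.items()
            if plist
        }
    else:
        proximity, proximity_null = None, None

    # --- write artefacts
    _write(qc_report.metrics.assign(
        status=["fail" if s in qc_report.reasons else "pass"
                for s in qc_report.metrics.index],
        reason=[qc_report.reasons.get(s, "") for s in qc_report.metrics.index],
    ), outdir / "qc_report.tsv", mhash)
    _write(expr.values, outdir / "expression.tsv", mhash)
    _write(scores, outdir / "scores.tsv", mhash)
    _write(calls, outdir / "subtype_calls.tsv", mhash)
    _write(rho, outdir / "score_spearman.tsv", mhash)
    _write(kappa, outdir / "score_kappa.tsv", mhash)
    if rho_sub is not None:
        _write(rho_sub, outdir / "subscore_spearman.tsv", mhash)
    if group_p is not None:
        flat = pd.concat(group_p, names=["score", "group"])
        _write(flat, outdir / "group_comparisons.tsv", mhash)
        _write(pd.concat(subtype_p, names=["score", "subtype"]),
               outdir / "subtype_comparisons.tsv", mhash)
        _write(summarize_cohort(annotations, calls), outdir / "cohort_summary.tsv", mhash)
    if proximity is not None:
        _write(
            pd.concat({k: v.table.set_index("sample_a") for k, v in proximity.items()},
                      names=["pair_type", "sample_a"]),
            outdir / "pair_proximity.tsv", mhash,
        )
    _write(pd.DataFrame({"leaf_order": clust.leaf_order}), outdir / "leaf_order.tsv",
           mhash)

    manifest["warnings"] = warnings
    manifest["n_samples"] = len(expr.samples)
    manifest["n_union_genes"] = len(union)
    manifest["n_reference_genes"] = len(refs)
    if proximity_null is not None:
        manifest["pair_proximity_null"] = proximity_null
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    results.update(
        counts=counts, annotations=annotations, truth=truth, qc=qc_report,
        expression=expr, scores=scores, calls=calls, spearman=rho,
        spearman_n=rho_n, kappa=kappa, subscore_spearman=rho_sub,
        group_comparisons=group_p, subtype_comparisons=subtype_p,
        discordance=discord, kappa_ihc=kappa_ihc, clustering=clust,
        proximity=proximity, proximity_null=proximity_null,
        union_genes=union, reference_genes=refs, manifest=manifest,
    )
    return results
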