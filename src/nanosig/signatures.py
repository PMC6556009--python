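"""Signature definitions, PAM50 centroid sets and the measured gene panel.

A multigene risk score is represented as a weighted sum of group scores:
``score = intercept + sum_g group_weight_g * group_score_g`` where each
group (proliferation, oestrogen response, progesterone, HER2, ...) is a
gene-weight-weighted mean of member gene expression. Each signature also
carries its own reference-gene set (scores are normalized against their
own housekeepers, not the pooled set) and an applicability rule (RS and
EP are only defined for ER+/HER2- tumours by IHC).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

SUBTYPES = ("normal", "lumA", "lumB", "Her2", "basal")
GROUP_NAMES = ("PRO", "ER", "PR", "HER2", "other")
APPLICABILITY = ("all", "er_pos_her2_neg")

__all__ = [
    "SUBTYPES",
    "SignatureDefinition",
    "SignatureGroup",
    "CentroidSet",
    "GenePanel",
    "load_signature",
    "load_centroids",
    "load_panel",
    "union_test_genes",
    "combined_reference_genes",
    "packaged_path",
    "load_packaged_signatures",
]


class SignatureError(ValueError):
    pass


def packaged_path(name: str) -> Path:
    """Path to a file shipped under ``nanosig/data``."""
    return Path(importlib.resources.files("nanosig") / "data" / name)


@dataclass
class SignatureGroup:
    name: str                                   # PRO/ER/PR/HER2/other
    members: list[tuple[str, float]]            # (gene_symbol, gene_weight)
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in GROUP_NAMES:
            raise SignatureError(f"unknown group name {self.name!r}")
        if not self.members:
            raise SignatureError(f"group {self.name!r} is empty")

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.members]


@dataclass
class SignatureDefinition:
    name: str
    groups: list[SignatureGroup]
    reference_genes: tuple[str, ...]
    applicability: str = "all"
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.applicability not in APPLICABILITY:
            raise SignatureError(f"unknown applicability {self.applicability!r}")
        genes = self.test_genes
        if len(genes) != len(set(genes)):
            dup = sorted({g for g in genes if genes.count(g) > 1})
            raise SignatureError(f"duplicate gene(s) in signature {self.name}: {dup}")
        overlap = set(genes) & set(self.reference_genes)
        if overlap:
            raise SignatureError(
                f"reference genes overlap test genes in {self.name}: {sorted(overlap)}"
            )

    @property
    def test_genes(self) -> list[str]:
        return [g for grp in self.groups for g in grp.genes]

    def group(self, name: str) -> SignatureGroup | None:
        for grp in self.groups:
            if grp.name == name:
                return grp
        return None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "applicability": self.applicability,
            "intercept": self.intercept,
            "reference_genes": list(self.reference_genes),
            "groups": [
                {
                    "name": g.name,
                    "weight": g.weight,
                    "members": [{"gene": m, "weight": w} for m, w in g.members],
                }
                for g in self.groups
            ],
        }


def _require(cfg: dict, key: str, context: str):
    if key not in cfg:
        raise SignatureError(f"signature config missing field {key!r} ({context})")
    return cfg[key]


def signature_from_dict(cfg: dict) -> SignatureDefinition:
    name = _require(cfg, "name", "top level")
    groups = []
    for gcfg in _require(cfg, "groups", name):
        members = [
            (str(_require(m, "gene", f"{name} group member")), float(m.get("weight", 1.0)))
            for m in _require(gcfg, "members", f"{name} groups")
        ]
        groups.append(
            SignatureGroup(
                name=str(_require(gcfg, "name", f"{name} groups")),
                members=members,
                weight=float(gcfg.get("weight", 1.0)),
            )
        )
    return SignatureDefinition(
        name=str(name),
        groups=groups,
        reference_genes=tuple(cfg.get("reference_genes", [])),
        applicability=str(cfg.get("applicability", "all")),
        intercept=float(cfg.get("intercept", 0.0)),
    )


def load_signature(path) -> SignatureDefinition:
    """Load and validate a signature definition from a YAML config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SignatureError(f"{path}: not a mapping")
    return signature_from_dict(cfg)


@dataclass
class CentroidSet:
    """Five-subtype centroid table plus risk-of-recurrence (ROR-P) weights.

    ``centroids`` is genes x subtypes; ``ror_coefficients`` maps each
    subtype to its correlation coefficient in the ROR-P linear combination,
    ``ror_pro_coefficient`` weights the mean expression of the
    ``proliferation_genes`` subset.
    """

    centroids: pd.DataFrame
    proliferation_genes: tuple[str, ...] = ()
    ror_coefficients: dict = field(default_factory=dict)
    ror_pro_coefficient: float = 0.0
    ror_intercept: float = 0.0
    reference_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        missing = [s for s in SUBTYPES if s not in self.centroids.columns]
        if missing:
            raise SignatureError(f"centroid table lacks subtype(s) {missing}")
        self.centroids = self.centroids[list(SUBTYPES)]
        stray = set(self.proliferation_genes) - set(self.centroids.index)
        if stray:
            raise SignatureError(
                f"proliferation genes outside centroid gene set: {sorted(stray)}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.centroids.index)

    # lets union_test_genes treat the classifier panel like a signature
    @property
    def test_genes(self) -> list[str]:
        return self.genes

    @property
    def name(self) -> str:
        return "PAM50"

    def drop_genes(self, genes) -> "CentroidSet":
        keep = [g for g in self.centroids.index if g not in set(genes)]
        return CentroidSet(
            centroids=self.centroids.loc[keep],
            proliferation_genes=tuple(
                g for g in self.proliferation_genes if g in keep
            ),
            ror_coefficients=self.ror_coefficients,
            ror_pro_coefficient=self.ror_pro_coefficient,
            ror_intercept=self.ror_intercept,
            reference_genes=self.reference_genes,
        )


def load_centroids(table_path, weights_path=None) -> CentroidSet:
    """Load a centroid TSV (gene rows, one column per subtype) and an
    optional YAML with ROR-P weights and the proliferation gene subset."""
    tab = pd.read_csv(table_path, sep="\t", index_col=0, comment="#")
    kwargs: dict = {}
    if weights_path is not None:
        with open(weights_path) as fh:
            w = yaml.safe_load(fh)
        kwargs = dict(
            proliferation_genes=tuple(w.get("proliferation_genes", [])),
            ror_coefficients={k: float(v) for k, v in w.get("coefficients", {}).items()},
            ror_pro_coefficient=float(w.get("pro_coefficient", 0.0)),
            ror_intercept=float(w.get("intercept", 0.0)),
            reference_genes=tuple(w.get("reference_genes", [])),
        )
    return CentroidSet(centroids=tab, **kwargs)


@dataclass
class GenePanel:
    """The measured CodeSet: test genes, reference genes, and genes declared
    by a signature but absent from the panel (e.g. CDC6/NUF2)."""

    test_genes: tuple[str, ...]
    reference_genes: tuple[str, ...]
    unmeasured_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        sets = [set(self.test_genes), set(self.reference_genes), set(self.unmeasured_genes)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise SignatureError(
                        f"panel gene categories overlap: {sorted(sets[i] & sets[j])}"
                    )

    @property
    def measured(self) -> set[str]:
        return set(self.test_genes) | set(self.reference_genes)


def load_panel(path) -> GenePanel:
    """Load a panel TSV with columns gene_symbol, category (test/reference/
    unmeasured), and optional score-membership annotation."""
    tab = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    need = {"gene_symbol", "category"}
    if not need <= set(tab.columns):
        raise SignatureError(f"panel table needs columns {sorted(need)}")
    by = {k: tuple(v["gene_symbol"]) for k, v in tab.groupby("category")}
    return GenePanel(
        test_genes=by.get("test", ()),
        reference_genes=by.get("reference", ()),
        unmeasured_genes=by.get("unmeasured", ()),
    )


def union_test_genes(signatures, panel: GenePanel | None = None) -> list[str]:
    """Sorted union of the signatures' test genes restricted to the measured
    panel (reference genes and declared-but-unmeasured genes excluded).

    Accepts any mix of SignatureDefinition and CentroidSet (both expose
    ``test_genes``).
    """
    if not signatures:
        raise SignatureError("union_test_genes needs at least one signature")
    union: set[str] = set()
    for sig in signatures:
        union |= set(sig.test_genes)
    if panel is not None:
        union &= set(panel.test_genes)
    else:
        # without a panel, still exclude any declared reference genes
        refs = set()
        for sig in signatures:
            refs |= set(getattr(sig, "reference_genes", ()))
        union -= refs
    return sorted(union)


def combined_reference_genes(signatures) -> list[str]:
    """Sorted union of the signatures' reference-gene sets."""
    refs: set[str] = set()
    for sig in signatures:
        refs |= set(getattr(sig, "reference_genes", ()))
    return sorted(refs)


def load_packaged_signatures() -> dict[str, SignatureDefinition]:
    """The shipped RISK/RS/EP definitions (RS transcribed from the published
    research-version algorithm; RISK and EP weights are synthetic stand-ins,
    see the files' comments)."""
    out = {}
    for fname in ("risk_synthetic.yaml", "rs.yaml", "ep_synthetic.yaml"):
        sig = load_signature(packaged_path(fname))
        out[sig.name] = sig
    return out


def load_packaged_centroids() -> CentroidSet:
    """The shipped synthetic five-subtype centroid set with ROR-P weights."""
    return load_centroids(
        packaged_path("pam50_centroids_synthetic.tsv"),
        packaged_path("ror_p_synthetic.yaml"),
    )


def load_packaged_panel() -> GenePanel:
    return load_panel(packaged_path("panel_synthetic.tsv"))
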