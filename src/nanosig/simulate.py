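"""Synthetic nCounter cohort generator.

Emulates the statistical structure of a breast-cancer cohort measured on a
custom nCounter CodeSet: 84 endogenous test genes, 12 housekeeping
(reference) genes, 8 negative-control and 6 positive-control probes;
five intrinsic subtypes (normal-like, luminal A/B, HER2-enriched,
basal-like) expressed as correlated gene programs (proliferation,
oestrogen response, the ERBB2/GRB7 amplicon, basal keratins, luminal
epithelial markers); five clinical groups (recurrence-free controls,
primaries of local recurrences, local recurrences, primaries of brain
metastases, brain metastases) with group sizes and subtype mixtures
mirroring the cohort table of the study this pipeline reproduces; and
matched primary/recurrence pairs whose molecular concordance is high for
brain metastases and low for local recurrences.

Counts are negative-binomial on the natural scale around
``library_size * 2**mu`` with ``mu`` the log2 mean built from a per-gene
base level, a per-subtype centroid deviation, per-group program shifts
and an individual (per-tumour) deviation shared within matched pairs.

The module is also the source of truth for the packaged synthetic panel
and centroid tables (``make_panel_table`` / ``make_centroid_table``):
those files are stand-ins, constructed here with documented separations,
for the proprietary assay definitions that cannot be redistributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ncounter import CountMatrix
from .signatures import (
    SUBTYPES,
    CentroidSet,
    GenePanel,
    load_packaged_centroids,
    packaged_path,
)

GROUPS = (
    "control",
    "primary_local",
    "local_recurrence",
    "primary_distant",
    "brain_metastasis",
)

# ---------------------------------------------------------------------------
# Panel composition (synthetic stand-in, structure matches the assay: the
# union of measured PAM50/RISK/RS/EP test genes is 74, total test genes 84,
# combined reference genes 12, CDC6 and NUF2 declared but unmeasured).

PAM50_GENES = (
    "ACTR3B ANLN BAG1 BCL2 BIRC5 BLVRA CCNB1 CCNE1 CDC20 CDC6 CDH3 CENPF "
    "CEP55 CXXC5 EGFR ERBB2 ESR1 EXO1 FGFR4 FOXA1 FOXC1 GPR160 GRB7 KIF2C "
    "KNTC2 KRT14 KRT17 KRT5 MAPT MDM2 MELK MIA MKI67 MLPH MMP11 MYBL2 MYC "
    "NAT1 NUF2 ORC6L PGR PHGDH PTTG1 RRM2 SFRP1 SLC39A6 TMEM45B TYMS UBE2C "
    "UBE2T"
).split()
UNMEASURED = ("CDC6", "NUF2")

RS_EXTRA = ("AURKA", "CTSL2", "SCUBE2", "GSTM1", "CD68")
EP_EXTRA = ("DHCR7", "RBBP8", "IL6ST", "AZGP1", "MGP", "STC2")
RISK_EXTRA = (
    "TOP2A RACGAP1 CDKN3 PCNA CCND1 GATA3 TFF1 TFF3 XBP1 IGF1R AR SCGB2A2 "
    "KRT18 CDH1 VEGFA"
).split()
PANEL_EXTRA = (
    "MLL3 KRT19 MUC1 EPCAM CLDN3 CLDN4 CD44 ALDH1A1 PTEN SNAI2"
).split()

REFERENCE_GENES = (
    "ACTB MRPL19 PSMC4 RPLP0 PUM1 GAPDH GUSB TFRC RPL13A CALM2 OAZ1 RPL37A"
).split()

NEGATIVE_PROBES = tuple(f"NEG_{c}" for c in "ABCDEFGH")
POSITIVE_PROBES = tuple(f"POS_{c}" for c in "ABCDEF")
POSITIVE_LADDER = (8192.0, 2048.0, 512.0, 128.0, 32.0, 8.0)

# Gene programs driving the subtype structure.
PROGRAMS: dict[str, tuple[str, ...]] = {
    "prolif": tuple(
        "ANLN BIRC5 CCNB1 CCNE1 CDC20 CDC6 CENPF CEP55 EXO1 KIF2C KNTC2 MELK "
        "MKI67 MYBL2 NUF2 ORC6L PTTG1 RRM2 TYMS UBE2C UBE2T AURKA TOP2A "
        "RACGAP1 CDKN3 PCNA DHCR7".split()
    ),
    "er": tuple(
        "ESR1 PGR BCL2 SCUBE2 FOXA1 GATA3 TFF1 TFF3 XBP1 AR SCGB2A2 MAPT "
        "NAT1 SLC39A6 MLPH IGF1R IL6ST AZGP1 MGP STC2 RBBP8 CXXC5 CCND1 BAG1 "
        "MDM2".split()
    ),
    "her2": ("ERBB2", "GRB7"),
    "basal": tuple(
        "KRT5 KRT14 KRT17 FOXC1 MIA CDH3 SFRP1 EGFR PHGDH ACTR3B CD44 "
        "ALDH1A1 SNAI2".split()
    ),
    "lumep": tuple("KRT18 KRT19 MUC1 EPCAM CLDN3 CLDN4 CDH1".split()),
}

# log2 program effect of each subtype (rows) on each program (columns).
_PROGRAM_EFFECTS = pd.DataFrame(
    {
        "prolif": [-1.2, -1.0, 0.8, 0.8, 1.2],
        "er": [0.2, 1.5, 1.0, -0.8, -1.5],
        "her2": [0.0, 0.0, 0.0, 2.5, -0.3],
        "basal": [0.5, -1.0, -1.0, -0.3, 2.0],
        "lumep": [-0.3, 0.8, 0.8, 0.2, -0.5],
    },
    index=list(SUBTYPES),
)

_PANEL_SEED = 20190607          # fixed: panel identity, independent of cohorts

ALL_TEST_GENES = tuple(
    [g for g in PAM50_GENES if g not in UNMEASURED]
    + list(RS_EXTRA)
    + list(EP_EXTRA)
    + list(RISK_EXTRA)
    + list(PANEL_EXTRA)
)


def _program_of(gene: str) -> str | None:
    for name, genes in PROGRAMS.items():
        if gene in genes:
            return name
    return None


def make_panel_table() -> pd.DataFrame:
    """The packaged panel table: gene, category, program membership and a
    fixed per-gene base log2 abundance (drawn once from a frozen seed)."""
    rng = np.random.default_rng(_PANEL_SEED)
    rows = []
    for g in ALL_TEST_GENES:
        rows.append((g, "test", _program_of(g) or "", rng.uniform(6.0, 9.0)))
    for g in UNMEASURED:
        rows.append((g, "unmeasured", _program_of(g) or "", np.nan))
    for g in REFERENCE_GENES:
        rows.append((g, "reference", "", rng.uniform(9.0, 10.5)))
    return pd.DataFrame(
        rows, columns=["gene_symbol", "category", "program", "base_log2"]
    )


def make_centroid_table() -> pd.DataFrame:
    """Synthetic five-subtype centroid deviations (log2, relative scale)
    over the 50 classifier genes: program effects plus a frozen per-gene
    per-subtype jitter so genes within a program carry distinct ranks."""
    rng = np.random.default_rng(_PANEL_SEED + 1)
    dev = pd.DataFrame(0.0, index=list(PAM50_GENES), columns=list(SUBTYPES))
    for g in PAM50_GENES:
        prog = _program_of(g)
        if prog is not None:
            dev.loc[g] += _PROGRAM_EFFECTS[prog].to_numpy()
        dev.loc[g] += rng.normal(0.0, 0.25, size=len(SUBTYPES))
    return dev.round(4)


# ---------------------------------------------------------------------------
# Generator configuration


def _table1_mixtures() -> dict[str, dict[str, float]]:
    counts = {
        "control": [2, 17, 14, 3, 7],
        "primary_local": [3, 9, 8, 4, 1],
        "local_recurrence": [0, 6, 9, 3, 2],
        "primary_distant": [1, 3, 2, 9, 4],
        "brain_metastasis": [0, 0, 4, 15, 6],
    }
    return {
        g: {s: c / sum(v) for s, c in zip(SUBTYPES, v)} for g, v in counts.items()
    }


@dataclass
class GeneratorConfig:
    """Study-condition defaults: cohort composition as in the reproduced
    study (43/25/20/19/25 tumours; 19 local and 19 brain matched pairs),
    brain-metastasis groups shifted +1.1 log2 (about +2 SD of the per-gene
    noise) in the proliferation program, negative-binomial dispersion 0.1."""

    group_sizes: dict = field(
        default_factory=lambda: {
            "control": 43,
            "primary_local": 25,
            "local_recurrence": 20,
            "primary_distant": 19,
            "brain_metastasis": 25,
        }
    )
    subtype_mixture: dict = field(default_factory=_table1_mixtures)
    group_shifts: dict = field(
        default_factory=lambda: {
            "primary_distant": {"prolif": 1.1},
            "brain_metastasis": {"prolif": 1.1},
        }
    )
    n_pairs: dict = field(default_factory=lambda: {"local": 19, "brain": 19})
    pair_subtype_concordance: dict = field(
        default_factory=lambda: {"local": 0.3, "brain": 0.9}
    )
    pair_profile_correlation: dict = field(
        default_factory=lambda: {"local": 0.2, "brain": 0.8}
    )
    dispersion: float = 0.1
    individual_sd: float = 0.3
    libsize_sigma: float = 0.25
    n_degraded: int = 0
    degraded_factor: float = 0.004
    seed: int = 0

    def validate(self) -> None:
        for g, mix in self.subtype_mixture.items():
            tot = sum(mix.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"subtype mixture for {g!r} sums to {tot}, not 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for kind, n in self.n_pairs.items():
            prim = "primary_local" if kind == "local" else "primary_distant"
            rec = "local_recurrence" if kind == "local" else "brain_metastasis"
            if n > min(self.group_sizes.get(prim, 0), self.group_sizes.get(rec, 0)):
                raise ValueError(f"more {kind} pairs than samples available")


def null_config(seed: int = 0, **kwargs) -> GeneratorConfig:
    """All groups share the control subtype mixture and no program shifts:
    every group is drawn from the same distribution (type-I calibration)."""
    mix = _table1_mixtures()["control"]
    return GeneratorConfig(
        subtype_mixture={g: dict(mix) for g in GROUPS},
        group_shifts={},
        seed=seed,
        **kwargs,
    )


def low_noise_config(n: int = 300, seed: int = 0) -> GeneratorConfig:
    """A single balanced group at low technical noise, for classifier
    recovery checks."""
    return GeneratorConfig(
        group_sizes={"control": n},
        subtype_mixture={"control": {s: 0.2 for s in SUBTYPES}},
        group_shifts={},
        n_pairs={},
        dispersion=0.02,
        individual_sd=0.1,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Cohort generation

_GROUP_PREFIX = {
    "control": "C",
    "primary_local": "PL",
    "local_recurrence": "LR",
    "primary_distant": "PD",
    "brain_metastasis": "BM",
}


def _load_panel_frame() -> pd.DataFrame:
    return pd.read_csv(packaged_path("panel_synthetic.tsv"), sep="\t", comment="#")


def generate_cohort(
    cfg: GeneratorConfig,
    panel: pd.DataFrame | None = None,
    centroids: CentroidSet | None = None,
):
    """Draw a full synthetic cohort.

    Returns ``(CountMatrix, annotations, truth)`` where annotations carries
    sample_id/group/pair_id plus IHC columns and truth the generator's
    ground truth (true subtype, program levels, degraded flags).
    """
    cfg.validate()
    panel = _load_panel_frame() if panel is None else panel
    centroids = load_packaged_centroids() if centroids is None else centroids
    rng = np.random.default_rng(cfg.seed)

    measured = panel[panel["category"] != "unmeasured"]
    test = measured[measured["category"] == "test"]
    refs = measured[measured["category"] == "reference"]
    genes = list(test["gene_symbol"])
    base = test.set_index("gene_symbol")["base_log2"]
    program = test.set_index("gene_symbol")["program"].fillna("")
    cent = centroids.centroids.reindex(genes)

    # non-PAM50 genes get their program effect directly (plus frozen jitter)
    jit_rng = np.random.default_rng(_PANEL_SEED + 2)
    for g in genes:
        if cent.loc[g].isna().any():
            prog = program[g]
            eff = (
                _PROGRAM_EFFECTS[prog]
                if prog in _PROGRAM_EFFECTS.columns
                else pd.Series(0.0, index=list(SUBTYPES))
            )
            cent.loc[g] = eff.to_numpy() + jit_rng.normal(0.0, 0.25, len(SUBTYPES))
        else:
            jit_rng.normal(0.0, 0.25, len(SUBTYPES))  # keep stream aligned

    prog_mask = {p: (program == p).to_numpy() for p in PROGRAMS}

    rows: list[dict] = []

    def draw_subtype(group: str) -> str:
        mix = cfg.subtype_mixture[group]
        return rng.choice(list(mix), p=np.array([mix[s] for s in mix]))

    def sample_row(sid, group, subtype, pair_id, dev, degraded=False):
        return {
            "sample_id": sid,
            "group": group,
            "subtype": subtype,
            "pair_id": pair_id,
            "dev": dev,
            "degraded": degraded,
        }

    pair_plan = {
        "local": ("primary_local", "local_recurrence"),
        "brain": ("primary_distant", "brain_metastasis"),
    }
    paired_recurrences: dict[str, dict] = {}

    for group in GROUPS:
        n = cfg.group_sizes.get(group, 0)
        prefix = _GROUP_PREFIX.get(group, group[:2].upper())
        for i in range(n):
            sid = f"{prefix}{i + 1:02d}"
            # recurrences paired to an earlier primary are drawn conditionally
            if sid in paired_recurrences:
                rows.append(paired_recurrences[sid])
                continue
            subtype = draw_subtype(group)
            dev = rng.normal(0.0, cfg.individual_sd, size=len(genes))
            pair_id = ""
            for kind, (prim_g, rec_g) in pair_plan.items():
                n_pairs = cfg.n_pairs.get(kind, 0)
                if group == prim_g and i < n_pairs:
                    pair_id = f"{kind[0].upper()}P{i + 1:02d}"
                    rec_sid = f"{_GROUP_PREFIX[rec_g]}{i + 1:02d}"
                    conc = cfg.pair_subtype_concordance.get(kind, 0.5)
                    rho = cfg.pair_profile_correlation.get(kind, 0.0)
                    rec_subtype = (
                        subtype if rng.random() < conc else draw_subtype(rec_g)
                    )
                    rec_dev = rho * dev + np.sqrt(1 - rho**2) * rng.normal(
                        0.0, cfg.individual_sd, size=len(genes)
                    )
                    paired_recurrences[rec_sid] = sample_row(
                        rec_sid, rec_g, rec_subtype, pair_id, rec_dev
                    )
            rows.append(sample_row(sid, group, subtype, pair_id, dev))

    active_groups = [g for g in GROUPS if cfg.group_sizes.get(g, 0) > 0]
    for i in range(cfg.n_degraded):
        group = active_groups[i % len(active_groups)]
        rows.append(
            sample_row(
                f"DG{i + 1:02d}",
                group,
                draw_subtype(group),
                "",
                rng.normal(0.0, cfg.individual_sd, size=len(genes)),
                degraded=True,
            )
        )

    # assemble count matrix
    n_genes = len(genes)
    sample_ids = [r["sample_id"] for r in rows]
    libsize = np.exp(rng.normal(0.0, cfg.libsize_sigma, size=len(rows)))

    mu = np.empty((n_genes, len(rows)))
    for j, r in enumerate(rows):
        m = base.to_numpy() + cent[r["subtype"]].to_numpy() + r["dev"]
        for prog, shift in cfg.group_shifts.get(r["group"], {}).items():
            m = m + shift * prog_mask[prog]
        mu[:, j] = m

    def nb(mean: np.ndarray) -> np.ndarray:
        mean = np.maximum(mean, 1e-6)
        r_ = 1.0 / cfg.dispersion
        p = r_ / (r_ + mean)
        return rng.negative_binomial(r_, p).astype(float)

    lib = np.where([r["degraded"] for r in rows], libsize * cfg.degraded_factor, libsize)
    endo_counts = nb(lib[None, :] * 2.0 ** mu)
    ref_mu = refs.set_index("gene_symbol")["base_log2"].to_numpy()
    ref_counts = nb(lib[None, :] * 2.0 ** ref_mu[:, None])
    neg_counts = rng.poisson(4.0, size=(len(NEGATIVE_PROBES), len(rows))).astype(float)
    pos_counts = rng.poisson(
        libsize[None, :] * np.asarray(POSITIVE_LADDER)[:, None]
    ).astype(float)

    probe_rows = (
        [(g, g, "endogenous") for g in genes]
        + [(g, g, "reference") for g in refs["gene_symbol"]]
        + [(p, p, "negative") for p in NEGATIVE_PROBES]
        + [(p, p, "positive") for p in POSITIVE_PROBES]
    )
    probes = pd.DataFrame(
        probe_rows, columns=["probe_id", "gene_symbol", "probe_class"]
    ).set_index("probe_id")
    counts = pd.DataFrame(
        np.vstack([endo_counts, ref_counts, neg_counts, pos_counts]),
        index=probes.index,
        columns=sample_ids,
    )
    cm = CountMatrix(probes=probes, counts=counts)

    prolif_idx = prog_mask["prolif"]
    er_idx = prog_mask["er"]
    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": [r["group"] for r in rows],
            "true_subtype": [r["subtype"] for r in rows],
            "pair_id": [r["pair_id"] for r in rows],
            "degraded": [r["degraded"] for r in rows],
            "prolif_level": mu[prolif_idx].mean(axis=0) - base[prolif_idx].mean(),
            "er_level": mu[er_idx].mean(axis=0) - base[er_idx].mean(),
        }
    ).set_index("sample_id")

    ihc = generate_ihc(truth, rng=rng)
    annotations = pd.concat(
        [truth[["group", "pair_id"]], ihc], axis=1
    ).reset_index()

    return cm, annotations.set_index("sample_id"), truth


# canonical IHC marker settings per true subtype (noise-free generation
# inverts the surrogate rule table exactly for the four non-normal classes)
_IHC_IDEAL = {
    "normal": dict(er=(60, 90), pr=(40, 80), her2="neg", ki67=(3, 12)),
    "lumA": dict(er=(60, 95), pr=(40, 90), her2="neg", ki67=(3, 12)),
    "lumB": dict(er=(50, 90), pr=(20, 80), her2="neg", ki67=(20, 70)),
    "Her2": dict(er=(0, 0.9), pr=(0, 0.9), her2="pos", ki67=(20, 80)),
    "basal": dict(er=(0, 0.9), pr=(0, 0.9), her2="neg", ki67=(30, 90)),
}


def generate_ihc(
    truth: pd.DataFrame,
    noise: float = 0.15,
    missing_rate: float = 0.02,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw ER/PR/HER2/Ki-67 IHC consistent with the true subtype.

    Each marker is independently randomized (drawn ignoring the subtype)
    with probability ``noise``; HER2 is reported as an unresolved 2+ and
    Ki-67 as missing with probability ``missing_rate`` each. At
    ``noise = 0, missing_rate = 0`` the surrogate rules recover every
    non-normal true subtype exactly.
    """
    if rng is None:
        rng = np.random.default_rng(seed)

    def pct(lo, hi):
        return float(np.round(rng.uniform(lo, hi), 1))

    def her2_cat(state: str) -> str:
        if state == "pos":
            return str(rng.choice(["3+", "FISH+"], p=[0.85, 0.15]))
        return str(rng.choice(["0", "1+", "FISH-"], p=[0.45, 0.45, 0.1]))

    recs = []
    for sid, row in truth.iterrows():
        ideal = _IHC_IDEAL[row["true_subtype"]]
        er = pct(*ideal["er"]) if rng.random() >= noise else pct(0, 95)
        pr = pct(*ideal["pr"]) if rng.random() >= noise else pct(0, 95)
        h_state = ideal["her2"] if rng.random() >= noise else rng.choice(["neg", "pos"])
        her2 = her2_cat(h_state)
        ki = pct(*ideal["ki67"]) if rng.random() >= noise else pct(0, 90)
        if rng.random() < missing_rate:
            her2 = "2+"
        if rng.random() < missing_rate:
            ki = np.nan
        recs.append((sid, er, pr, her2, ki))
    return pd.DataFrame(
        recs, columns=["sample_id", "er_percent", "pr_percent", "her2", "ki67_li"]
    ).set_index("sample_id")
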