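#!/usr/bin/env python
"""Concordance between scores and comparisons across clinical groups.

On primary tumours: pairwise Spearman correlations and tertile-
dichotomized Cohen's kappa between the four scores, and the PRO- vs
ER-subscore correlation contrast. Across all five groups: pairwise
Mann-Whitney tests per score and subscore, plus score-by-PAM50-subtype
comparisons and a per-gene screen of controls vs local-recurrence
primaries.
"""

import itertools
from pathlib import Path

import pandas as pd

from nanosig import ncounter, stats
from nanosig.simulate import GROUPS

DATA = Path("results/data")
OUT = Path("results")
SCORES = ["RISK", "RS", "ROR-P", "EP"]

if __name__ == "__main__":
    scores = pd.read_csv(OUT / "scores.tsv", sep="\t", index_col="sample_id")
    calls = pd.read_csv(OUT / "subtype_calls.tsv", sep="\t", index_col="sample_id")
    ann = pd.read_csv(DATA / "annotations.tsv", sep="\t", index_col="sample_id")
    ann = ann.loc[scores.index]

    primaries = ann["group"].isin(["control", "primary_local", "primary_distant"])
    prim = scores[primaries]

    rho, _ = stats.spearman_matrix(prim[SCORES])
    rho.to_csv(OUT / "score_spearman.tsv", sep="\t")
    kappas = {}
    for a, b in itertools.combinations(SCORES, 2):
        sub = prim[[a, b]].dropna()
        kappas[f"{a}|{b}"] = stats.cohens_kappa(
            stats.tertile_dichotomize(sub[a]), stats.tertile_dichotomize(sub[b])
        )
    pairs = list(itertools.combinations(SCORES, 2))
    print("score concordance on primaries: rho "
          f"{min(rho.loc[a, b] for a, b in pairs):.2f}-"
          f"{max(rho.loc[a, b] for a, b in pairs):.2f}, "
          f"kappa {min(kappas.values()):.2f}-{max(kappas.values()):.2f}")

    pro = [c for c in scores.columns if c.endswith("_PRO")]
    er = [c for c in scores.columns if c.endswith("_ER")]
    rho_pro, _ = stats.spearman_matrix(prim[pro])
    rho_er, _ = stats.spearman_matrix(prim[er])
    pro_vals = [rho_pro.loc[a, b] for a, b in itertools.combinations(pro, 2)]
    er_vals = [rho_er.loc[a, b] for a, b in itertools.combinations(er, 2)]
    print(f"PRO-subscore rho >= {min(pro_vals):.2f}; "
          f"ER-subscore rho {min(er_vals):.2f}-{max(er_vals):.2f} "
          "(proliferation drives the agreement between scores)")

    comp = stats.group_comparisons(scores, ann["group"], group_order=list(GROUPS))
    pd.concat(comp, names=["score", "group"]).to_csv(
        OUT / "group_comparisons.tsv", sep="\t"
    )
    for s in ("RISK", "ROR-P"):
        print(f"{s}: control vs brain-met primary p = "
              f"{comp[s].loc['control', 'primary_distant']:.2g}; "
              f"control vs local-rec primary p = "
              f"{comp[s].loc['control', 'primary_local']:.2f}")

    by_subtype = stats.group_comparisons(
        prim[SCORES], calls.loc[prim.index, "pam50"],
        group_order=["normal", "lumA", "lumB", "Her2", "basal"],
    )
    pd.concat(by_subtype, names=["score", "subtype"]).to_csv(
        OUT / "subtype_comparisons.tsv", sep="\t"
    )

    expr = pd.read_csv(OUT / "expression.tsv", sep="\t", index_col=0)
    cm = ncounter.read_counts(DATA / "counts.tsv")
    endo = cm.probes.loc[cm.probes["probe_class"] == "endogenous", "gene_symbol"]
    per_gene = stats.per_gene_comparison(
        expr.loc[[g for g in endo if g in expr.index]],
        ann["group"], ("control", "primary_local"),
    )
    per_gene.to_csv(OUT / "per_gene_control_vs_local.tsv", sep="\t")
    top = per_gene.head(3)
    print("top genes, control vs local-recurrence primaries:",
          {g: f"p={p:.3f}" for g, p in top["p"].items()})
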