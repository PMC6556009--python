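#!/usr/bin/env python
"""QC-filter and normalize the raw counts.

Background-corrects against the negative controls, scales by the
positive-control geometric means, drops poor-quality samples, and
normalizes against the combined 12-gene reference set (5 classifier + 3
RISK + 5 RS + 3 EP housekeepers, overlapping). Writes the QC report and
the log2 expression matrix.
"""

from pathlib import Path

from nanosig import ncounter
from nanosig.signatures import (
    combined_reference_genes,
    load_packaged_centroids,
    load_packaged_signatures,
)

DATA = Path("results/data")
OUT = Path("results")

if __name__ == "__main__":
    cm = ncounter.read_counts(DATA / "counts.tsv")
    kept, qc = ncounter.qc_filter(cm)
    for s in qc.excluded:
        print(f"excluded {s}: {qc.reasons[s]}")
    refs = combined_reference_genes(
        list(load_packaged_signatures().values()) + [load_packaged_centroids()]
    )
    expr = ncounter.normalize(kept, refs)
    qc.metrics.to_csv(OUT / "qc_report.tsv", sep="\t")
    expr.values.to_csv(OUT / "expression.tsv", sep="\t")
    print(f"{len(expr.samples)} samples normalized against "
          f"{len(refs)} reference genes -> {OUT / 'expression.tsv'}")
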