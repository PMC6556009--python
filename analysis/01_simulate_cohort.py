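#!/usr/bin/env python
"""Generate the study cohort.

Draws the default synthetic cohort: 43 recurrence-free controls, 25
primaries of local recurrences, 20 local recurrences, 19 primaries of
brain metastases and 25 brain metastases (19 matched pairs of each kind),
plus 7 degraded samples destined to fail QC — 139 raw samples on a
110-probe nCounter-style panel. Writes the raw count table, the sample
annotations (group, pair id, IHC markers) and the generator ground truth.
"""

from pathlib import Path

from nanosig import ncounter
from nanosig.simulate import GeneratorConfig, generate_cohort

OUT = Path("results/data")
SEED = 0

if __name__ == "__main__":
    cfg = GeneratorConfig(seed=SEED, n_degraded=7)
    cm, ann, truth = generate_cohort(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    ncounter.write_counts(cm, OUT / "counts.tsv")
    ann.to_csv(OUT / "annotations.tsv", sep="\t")
    truth.to_csv(OUT / "truth.tsv", sep="\t")
    by_group = ann["group"].value_counts().to_dict()
    print(f"wrote {len(cm.samples)} raw samples ({by_group}) "
          f"and {len(cm.probes)} probes to {OUT}")
    print(f"{int(truth['degraded'].sum())} degraded samples planted for QC")
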