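# Risk-of-recurrence (ROR-P) weights: per-subtype centroid-correlation
# coefficients plus a proliferation term (mean expression of the
# proliferation gene subset of the classifier). Coefficients are SYNTHETIC
# stand-ins with the published score's sign structure (luminal-A
# correlation lowers risk, basal/HER2 correlation and proliferation raise
# it). CDC6 and NUF2 are in the subset but unmeasured on this panel; they
# are dropped at computation time with a warning.
reference_genes: [ACTB, MRPL19, PSMC4, RPLP0, PUM1]
intercept: 0.0
pro_coefficient: 0.5
coefficients:
  normal: -0.35
  lumA: -0.65
  lumB: 0.15
  Her2: 0.35
  basal: 0.6
proliferation_genes:
  [ANLN, BIRC5, CCNE1, CDC20, CDC6, CEP55, EXO1, KIF2C, KNTC2, MELK,
   MKI67, NUF2, ORC6L, PTTG1, RRM2, TYMS, UBE2C, UBE2T]
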