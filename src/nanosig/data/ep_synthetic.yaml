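# EndoPredict-style risk score for ER+/HER2- tumours. Gene membership is
# the published 8 genes of interest + 3 reference genes; the numeric
# weights here are SYNTHETIC stand-ins (sign structure preserved:
# proliferation genes add risk, oestrogen-response genes reduce it), not a
# transcription of the proprietary coefficients.
name: EP
applicability: er_pos_her2_neg
intercept: 0.0
reference_genes: [CALM2, OAZ1, RPL37A]
groups:
  - name: PRO
    weight: 1.2
    members:
      - {gene: BIRC5, weight: 1.0}
      - {gene: UBE2C, weight: 1.0}
      - {gene: DHCR7, weight: 0.6}
  - name: ER
    weight: -1.0
    members:
      - {gene: RBBP8, weight: 1.0}
      - {gene: IL6ST, weight: 0.6}
      - {gene: AZGP1, weight: 0.8}
      - {gene: MGP, weight: 0.5}
      - {gene: STC2, weight: 0.9}
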