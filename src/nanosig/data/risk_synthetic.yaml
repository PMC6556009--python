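# RISK-style disease-free-survival score applicable to all tumours:
# proliferation, oestrogen-response, progesterone and ERBB2/GRB7 groups.
# The gene membership and all weights are SYNTHETIC stand-ins with the
# published score's group structure (PRO adds risk; ER/PR responsiveness
# reduces it; the HER2 amplicon adds risk), not a transcription.
name: RISK
applicability: all
intercept: 0.0
reference_genes: [ACTB, GAPDH, RPL13A]
groups:
  - name: PRO
    weight: 1.0
    members:
      - {gene: MKI67, weight: 1.0}
      - {gene: AURKA, weight: 1.0}
      - {gene: UBE2C, weight: 1.0}
      - {gene: TOP2A, weight: 1.0}
      - {gene: RACGAP1, weight: 1.0}
      - {gene: CDKN3, weight: 1.0}
      - {gene: PCNA, weight: 1.0}
      - {gene: CCND1, weight: 1.0}
  - name: ER
    weight: -0.6
    members:
      - {gene: ESR1, weight: 1.0}
      - {gene: GATA3, weight: 1.0}
      - {gene: FOXA1, weight: 1.0}
      - {gene: TFF1, weight: 1.0}
      - {gene: TFF3, weight: 1.0}
      - {gene: XBP1, weight: 1.0}
      - {gene: IGF1R, weight: 1.0}
  - name: PR
    weight: -0.4
    members:
      - {gene: PGR, weight: 1.0}
      - {gene: AR, weight: 1.0}
      - {gene: SCGB2A2, weight: 1.0}
  - name: HER2
    weight: 0.4
    members:
      - {gene: ERBB2, weight: 1.0}
      - {gene: GRB7, weight: 1.0}
  - name: other
    weight: -0.2
    members:
      - {gene: KRT18, weight: 1.0}
      - {gene: CDH1, weight: 1.0}
      - {gene: VEGFA, weight: 1.0}
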