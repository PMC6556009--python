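# 21-gene recurrence score, research version: the published unscaled
# group-score linear combination (HER2, ER, proliferation, invasion groups
# plus CD68/GSTM1/BAG1), WITHOUT group-score threshold cutoffs and without
# the 0-100 rescaling. Five housekeeping reference genes.
name: RS
applicability: er_pos_her2_neg
intercept: 0.0
reference_genes: [ACTB, GAPDH, RPLP0, GUSB, TFRC]
groups:
  - name: HER2
    weight: 0.47
    members:
      - {gene: GRB7, weight: 0.9}
      - {gene: ERBB2, weight: 0.1}
  - name: ER
    weight: -0.34
    members:
      - {gene: ESR1, weight: 0.8}
      - {gene: PGR, weight: 1.2}
      - {gene: BCL2, weight: 1.0}
      - {gene: SCUBE2, weight: 1.0}
  - name: PRO
    weight: 1.04
    members:
      - {gene: MKI67, weight: 1.0}
      - {gene: AURKA, weight: 1.0}
      - {gene: BIRC5, weight: 1.0}
      - {gene: CCNB1, weight: 1.0}
      - {gene: MYBL2, weight: 1.0}
  - name: other   # invasion group
    weight: 0.10
    members:
      - {gene: MMP11, weight: 1.0}
      - {gene: CTSL2, weight: 1.0}
  - name: other
    weight: 0.05
    members:
      - {gene: CD68, weight: 1.0}
  - name: other
    weight: -0.08
    members:
      - {gene: GSTM1, weight: 1.0}
  - name: other
    weight: -0.07
    members:
      - {gene: BAG1, weight: 1.0}
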