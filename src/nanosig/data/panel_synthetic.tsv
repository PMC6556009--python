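# SYNTHETIC stand-in panel: real gene symbols, assay-matched structure (84 test + 12 reference genes,
# CDC6/NUF2 declared but unmeasured); base_log2 abundances and program labels are generator constructs.
gene_symbol	category	program	base_log2
ACTR3B	test	basal	6.9573
ANLN	test	prolif	8.8744
BAG1	test	er	8.1741
BCL2	test	er	7.9411
BIRC5	test	prolif	6.6901
BLVRA	test		8.2751
CCNB1	test	prolif	8.7904
CCNE1	test	prolif	8.5909
CDC20	test	prolif	7.3125
CDH3	test	basal	6.2942
CENPF	test	prolif	6.8022
CEP55	test	prolif	6.9392
CXXC5	test	er	7.9993
EGFR	test	basal	6.9746
ERBB2	test	her2	8.2509
ESR1	test	er	8.1119
EXO1	test	prolif	6.4091
FGFR4	test		8.8376
FOXA1	test	er	8.2708
FOXC1	test	basal	7.7757
GPR160	test		6.9208
GRB7	test	her2	8.0956
KIF2C	test	prolif	8.9493
KNTC2	test	prolif	7.5409
KRT14	test	basal	8.6237
KRT17	test	basal	6.2056
KRT5	test	basal	6.8175
MAPT	test	er	8.8724
MDM2	test	er	6.2105
MELK	test	prolif	7.8089
MIA	test	basal	8.8458
MKI67	test	prolif	6.0981
MLPH	test	er	8.2468
MMP11	test		7.1998
MYBL2	test	prolif	6.3470
MYC	test		7.4421
NAT1	test	er	8.6939
ORC6L	test	prolif	8.2319
PGR	test	er	7.2055
PHGDH	test	basal	8.8355
PTTG1	test	prolif	6.0454
RRM2	test	prolif	6.3690
SFRP1	test	basal	7.1505
SLC39A6	test	er	8.9586
TMEM45B	test		7.8782
TYMS	test	prolif	6.6916
UBE2C	test	prolif	8.4437
UBE2T	test	prolif	8.1268
AURKA	test	prolif	7.5407
CTSL2	test		6.4359
SCUBE2	test	er	8.9938
GSTM1	test		8.8256
CD68	test		7.2408
DHCR7	test	prolif	8.2828
RBBP8	test	er	8.9358
IL6ST	test	er	7.3725
AZGP1	test	er	8.1838
MGP	test	er	7.2305
STC2	test	er	7.9238
TOP2A	test	prolif	6.2092
RACGAP1	test	prolif	7.2309
CDKN3	test	prolif	7.2335
PCNA	test	prolif	7.4432
CCND1	test	er	6.8216
GATA3	test	er	8.6098
TFF1	test	er	6.6699
TFF3	test	er	7.7570
XBP1	test	er	6.3400
IGF1R	test	er	8.9970
AR	test	er	7.3976
SCGB2A2	test	er	7.0839
KRT18	test	lumep	6.8952
CDH1	test	lumep	7.5497
VEGFA	test		7.6968
MLL3	test		7.5920
KRT19	test	lumep	6.6788
MUC1	test	lumep	8.6252
EPCAM	test	lumep	8.2662
CLDN3	test	lumep	6.3329
CLDN4	test	lumep	7.3031
CD44	test	basal	6.9426
ALDH1A1	test	basal	6.9031
PTEN	test		6.1360
SNAI2	test	basal	6.4605
CDC6	unmeasured	prolif	
NUF2	unmeasured	prolif	
ACTB	reference		9.6356
MRPL19	reference		10.4252
PSMC4	reference		9.3644
RPLP0	reference		9.4809
PUM1	reference		9.0527
GAPDH	reference		9.1128
GUSB	reference		9.8491
TFRC	reference		9.6402
RPL13A	reference		10.3121
CALM2	reference		10.2241
OAZ1	reference		9.4554
RPL37A	reference		10.3677
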