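# SYNTHETIC five-subtype centroid deviations (log2, relative scale) over the 50 classifier genes;
# constructed from documented program separations, NOT the published centroids.
	normal	lumA	lumB	Her2	basal
ACTR3B	0.8596	-1.5788	-1.3964	-0.1728	1.5792
ANLN	-1.0852	-0.8692	0.5827	0.7969	1.2814
BAG1	0.422	1.5534	1.1695	-0.8189	-1.4105
BCL2	0.3013	1.5904	0.974	-0.8717	-1.6073
BIRC5	-1.2785	-1.0493	0.6301	0.5832	1.2432
BLVRA	0.3272	-0.2261	-0.1495	-0.1652	-0.4412
CCNB1	-1.2758	-0.6908	0.8292	1.1556	1.6055
CCNE1	-1.3786	-0.835	0.6732	0.8512	1.3242
CDC20	-1.1544	-0.9488	0.9024	0.6486	1.4599
CDC6	-1.1354	-1.0805	0.778	0.9135	1.1427
CDH3	0.7627	-0.851	-1.3876	-0.6142	2.1384
CENPF	-1.751	-1.1074	0.3436	0.6353	1.1354
CEP55	-1.1827	-0.8121	1.1135	0.7955	0.9426
CXXC5	0.535	1.8888	0.9534	-1.1466	-1.4874
EGFR	0.8937	-0.9087	-1.19	-0.5962	2.2814
ERBB2	0.1855	-0.2259	-0.0754	2.3055	-0.0265
ESR1	0.2976	1.1347	0.8041	-0.82	-1.4644
EXO1	-1.2056	-0.7974	0.6175	0.4059	0.9145
FGFR4	0.217	0.0919	-0.0621	0.0617	0.0578
FOXA1	0.76	1.1767	0.7902	-0.9615	-1.5541
FOXC1	0.4856	-1.3204	-1.0226	-0.0265	2.2756
GPR160	-0.0757	0.0048	0.1367	-0.0482	0.144
GRB7	0.4522	-0.1118	-0.2347	2.5427	0.0307
KIF2C	-1.0632	-0.5416	0.8539	0.6362	1.056
KNTC2	-0.9559	-1.2875	0.9916	0.7563	1.2696
KRT14	0.2507	-1.1753	-1.0251	-0.08	1.8409
KRT17	0.5916	-1.0587	-1.8083	-0.2385	1.6657
KRT5	0.549	-0.9171	-1.2478	-0.1041	1.965
MAPT	0.3341	1.2478	1.2496	-0.7768	-1.429
MDM2	0.3585	0.9879	1.2382	-0.6715	-1.5167
MELK	-1.2049	-1.1172	1.1355	0.6574	1.0123
MIA	0.6994	-1.1285	-0.8945	0.1438	1.9369
MKI67	-1.0543	-0.7341	0.4496	0.5215	1.4452
MLPH	0.5867	1.8738	1.2656	-0.8726	-1.1021
MMP11	0.555	0.208	-0.1274	-0.1689	0.0465
MYBL2	-1.3212	-0.5817	1.2252	0.9226	1.0106
MYC	0.0319	0.0005	0.1306	0.0987	-0.0411
NAT1	-0.0035	1.4276	0.7391	-0.2008	-1.3638
NUF2	-1.0954	-0.7121	0.9053	1.147	1.8312
ORC6L	-0.5665	-1.097	0.6882	0.6274	1.0797
PGR	0.396	1.207	0.801	-1.1074	-1.7076
PHGDH	0.3252	-1.0317	-1.1323	-0.4197	1.872
PTTG1	-1.5514	-0.7458	0.882	0.6911	1.3498
RRM2	-0.9606	-0.644	1.3367	0.2431	1.0141
SFRP1	0.3578	-1.1602	-0.9254	-0.7331	2.1927
SLC39A6	0.2441	1.5104	0.7433	-0.69	-1.3203
TMEM45B	-0.3464	0.0166	-0.1866	-0.2681	0.1555
TYMS	-0.8607	-1.0198	1.2251	0.6872	1.2318
UBE2C	-0.8134	-0.916	0.6737	0.397	0.9996
UBE2T	-1.2885	-0.7012	1.1682	0.801	0.9023
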