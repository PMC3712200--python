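gene	pattern	fold	p	hazard_ratio
HMBS	down	-2.06	0.00225	1.41
GMPPA	down	-2.80	0.00283	1.46
CD79A	down	-1.27	0.00431	0.72
HSPA12A	down	-1.18	0.00759	1.43
RUNX3	down	-1.19	0.00818	0.71
RBKS	down	-1.17	0.0123	1.47
LRRC20	down	-2.88	0.0132	1.47
RNF144A	down	-1.37	0.0136	0.75
C11orf60	down	-1.30	0.0148	1.36
BCS1L	down	-1.12	0.0149	1.32
CHST12	down	-2.05	0.0155	0.75
CRYBB2P1	down	-1.09	0.0172	0.75
APITD1	down	-2.35	0.0176	1.35
AP1G2	down	-1.62	0.0177	1.39
ALDH3B1	down	-1.77	0.0185	1.36
AUTS2	down	-1.89	0.0210	0.74
NIPSNAP1	down	-1.64	0.0229	1.29
LCMT1	down	-1.69	0.0240	1.29
HERC6	down	-1.18	0.0250	0.75
DYRK4	down	-1.21	0.0261	0.77
TPD52L1	down	-1.30	0.0262	1.35
VPS33B	down	-1.05	0.0274	1.32
DHRS1	down	-1.83	0.0280	1.28
WDR61	down	-1.26	0.0292	1.32
PYGL	down	-1.62	0.0314	1.31
MKS1	down	-1.08	0.0316	1.29
VASH1	down	-4.29	0.0336	0.77
MRPL46	down	-1.52	0.0338	1.29
APBA2	down	-2.56	0.0340	0.75
LARGE	down	-2.96	0.0341	0.76
IMP3	down	-1.40	0.0354	1.28
AAAS	down	-1.55	0.0354	0.78
TGIF1	down	-1.41	0.0359	1.26
C11orf80	down	-1.03	0.0363	1.32
AGAP11	down	-1.51	0.0387	1.33
CCR7	down	-4.47	0.0390	0.78
RRBP1	down	-1.05	0.0395	0.77
CDC123	down	-1.09	0.0422	1.29
REEP4	down	-1.48	0.0433	1.28
PFKFB1	down	-1.40	0.0433	0.78
ZNF839	down	-2.28	0.0440	1.3
CCDC53	down	-1.88	0.0460	0.80
RDX	down	-1.22	0.0466	1.29
EIF2B3	down	-2.05	0.0470	1.27
PAAF1	down	-1.81	0.0471	1.35
PITPNC1	down	-1.39	0.0483	1.29
ATIC	down	-1.31	0.0492	1.27
DDX28	down	-1.63	0.0498	1.28
YPEL5	up	1.99	0.000577	0.62
MNT	up	1.56	0.00344	1.42
GGA3	up	1.11	0.00421	1.40
MGC29506	up	1.00	0.00471	0.72
CHD7	up	1.63	0.00763	1.49
ERCC6	up	1.52	0.00887	1.37
SSBP2	up	1.61	0.0122	0.72
NUFIP1	up	1.41	0.0129	1.33
CLK3	up	1.04	0.0159	1.37
PPP1R13L	up	2.74	0.0160	1.35
TNFSF9	up	1.92	0.0162	1.34
DDX52	up	1.80	0.0163	1.36
FAM108B1	up	1.33	0.0192	0.73
ZMYM5	up	1.23	0.0203	1.32
PTPRH	up	1.89	0.0217	1.34
BTG2	up	3.33	0.0231	0.74
ARHGEF15	up	1.52	0.0233	1.3
SPATA2L	up	1.68	0.0244	1.30
PRKRIP1	up	1.56	0.0245	0.76
KIFC1	up	1.47	0.0247	1.32
RUNX1	up	2.83	0.0247	1.32
GOLGA8A	up	2.02	0.0249	0.72
ABL1	up	1.15	0.0254	0.76
CRABP2	up	2.34	0.0258	0.75
DDIT3	up	4.91	0.0260	1.34
IP6K2	up	2.19	0.0273	0.76
LOC729806	up	1.2	0.0275	1.36
ELL	up	2.63	0.0284	0.79
TRAF4	up	1.00	0.0294	1.39
SEMA7A	up	1.16	0.0297	1.31
PRNP	up	1.51	0.0303	0.75
GADD45A	up	4.03	0.0314	0.76
GLIPR1	up	1.94	0.0330	0.77
PAPOLG	up	1.93	0.0331	0.75
ZNF484	up	2.81	0.0336	1.36
RAP2C	up	1.46	0.0336	0.76
MED1	up	1.25	0.0389	1.24
HERPUD1	up	1.01	0.0392	0.79
DDR2	up	1.11	0.0404	0.79
PLK4	up	1.59	0.0417	1.30
CDC42SE1	up	2.29	0.0417	0.76
AOC2	up	1.09	0.0430	1.29
RUNX2	up	1.80	0.0438	1.29
SFRS12IP1	up	1.81	0.0451	0.76
INPP1	up	1.40	0.0456	0.76
MCAM	up	1.57	0.0458	0.79
LTB	up	4.85	0.0470	0.77
ZCCHC10	up	1.13	0.0480	0.79
SP2	up	1.59	0.0489	0.79
PTHLH	up	2.81	0.0499	0.79
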