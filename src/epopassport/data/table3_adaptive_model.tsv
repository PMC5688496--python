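marker	kind	mean	sigma2_within	sigma2_between	sensitivity_pct	specificity_pct	roc_area
HGB	blood	150	29	36	79	93	0.87
OFF-score	blood	92	51	62	93	93	0.93
ADIPOR1	transcript	3.33	0.098	0.085	86	79	0.97
ALAS2	transcript	3.09	0.204	0.282	100	79	0.97
BCL2L1	transcript	1.33	0.159	0.202	93	93	0.96
BPGM	transcript	2.74	0.107	0.087	93	71	0.98
CA1	transcript	1.28	0.159	0.190	93	79	0.97
CCR7	transcript	-0.15	0.092	0.155	29	93	0.78
CD247	transcript	-0.66	0.059	0.046	43	71	0.62
CD3D	transcript	0.30	0.061	0.048	43	64	0.63
CSDA	transcript	2.68	0.136	0.150	93	93	0.98
DCAF12	transcript	2.18	0.146	0.198	93	79	0.98
EEF1D	transcript	1.75	0.026	0.027	43	64	0.63
EPB42	transcript	-0.91	0.243	0.448	93	86	0.96
FAM46C	transcript	3.74	0.083	0.061	93	79	0.95
FBXO7	transcript	3.54	0.079	0.075	79	79	0.92
FECH	transcript	1.34	0.142	0.119	86	71	0.95
GMPR	transcript	0.23	0.181	0.281	86	86	0.93
GUK1	transcript	0.51	0.130	0.228	86	79	0.95
GYPE	transcript	-4.87	0.145	0.282	79	93	0.92
HBD	transcript	0.20	0.243	0.885	64	64	0.95
KRT1	transcript	-1.31	0.327	1.229	86	71	0.86
LEF1	transcript	0.37	0.083	0.129	36	93	0.68
LOC100130562	transcript	2.78	0.032	0.027	50	71	0.63
LOC286444	transcript	0.73	0.034	0.049	50	79	0.69
MIF	transcript	-0.15	0.043	0.021	36	71	0.62
OSBP2	transcript	0.61	0.205	0.206	93	79	0.97
PITHD1	transcript	0.20	0.125	0.183	86	86	0.92
RBM38	transcript	0.44	0.150	0.566	79	79	0.89
RNF213	transcript	0.76	0.102	0.062	36	79	0.42
SELENBP1	transcript	0.63	0.240	0.401	93	79	0.92
SGK223	transcript	-2.81	0.064	0.042	36	79	0.60
SKAP1	transcript	-1.52	0.055	0.052	43	79	0.61
SLC4A1	transcript	1.36	0.213	0.595	93	86	0.96
SNCA	transcript	0.87	0.172	0.154	86	71	0.96
STRADB	transcript	2.29	0.136	0.145	93	86	0.99
TMOD1	transcript	-0.57	0.188	0.163	93	71	0.95
TNS1	transcript	-2.05	0.234	0.306	93	86	0.96
TPRA1	transcript	-2.43	0.011	0.010	50	79	0.67
TRIM58	transcript	2.23	0.156	0.199	86	71	0.98
UBXN6	transcript	2.06	0.107	0.209	93	71	0.98
VEGFB	transcript	-1.62	0.045	0.039	57	64	0.67
YOD1	transcript	1.48	0.137	0.050	71	71	0.90
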