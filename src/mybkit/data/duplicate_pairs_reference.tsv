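# Published Ka/Ks estimates and molecular-clock dates for MYB duplicate
# gene pairs in the Capsicum chinense genome; regression fixture for the
# ratio and dating arithmetic (lambda = 6.96e-9 syn subs/site/year).
gene_a	gene_b	mode	ka	ks	ratio	t_mya
CcAPL3	CcAPL2	Segmental	0.131	0.526	0.248	37.77
CcARR1	CcARR2	Segmental	0.167	0.834	0.200	59.92
CcARR9	CcARR8	Tandem	0.092	0.118	0.778	8.50
CcDIV10-1	CcDIV10-2	Tandem	0.078	0.117	0.668	8.43
CcDIV11	CcSRM1	Segmental	0.427	3.501	0.122	251.48
CcDIV4	CcDIV8	Segmental	0.164	1.008	0.163	72.43
CcDIV6-2	CcDIV6-1	Tandem	0.091	0.108	0.840	7.77
CcDIV7	CcSRM1	Segmental	0.456	2.903	0.157	208.54
CcGLK1-1	CcGLK1-2	Segmental	0.000	0.003	0.001	0.24
CcGLK1-1	CcGLK1-3	Segmental	0.000	0.003	0.001	0.24
CcGLK1-1	CcGLK1-4	Segmental	0.000	0.003	0.001	0.24
CcGLK1-2	CcGLK1-3	Segmental	NA	NA	NA	NA
CcGLK1-2	CcGLK1-4	Segmental	NA	NA	NA	NA
CcGLK1-4	CcGLK1-3	Segmental	NA	NA	NA	NA
CcMYB102	CcMYB122	Segmental	0.235	1.185	0.198	85.10
CcMYB106	CcMYB102	Segmental	0.254	4.157	0.061	298.60
CcMYB106	CcMYB101	Segmental	0.346	3.527	0.098	253.35
CcMYB106	CcMYB122	Segmental	0.334	4.018	0.083	288.64
CcMYB106	CcMYB104	Segmental	0.336	4.312	0.078	309.78
CcMYB110	CcMYB111	Tandem	0.014	0.083	0.164	5.94
CcMYB115	CcA	Segmental	0.369	0.993	0.372	71.32
CcMYB14	CcMYB16	Segmental	0.396	2.037	0.195	146.36
CcMYB25	CcMYB26	Tandem	0.035	0.136	0.261	9.74
CcMYB31	CcMYB63	Tandem	0.137	0.456	0.300	32.76
CcMYB31	CcMYB65	Tandem	0.184	0.529	0.349	37.99
CcMYB32	CcMYB33	Segmental	0.134	0.783	0.172	56.24
CcMYB55	CcMYB54	Segmental	0.233	2.843	0.082	204.22
CcMYB60-1	CcMYB60-2	Segmental	0.061	0.060	1.027	4.29
CcMYB64	CcMYB31	Tandem	0.090	0.334	0.269	23.98
CcMYB64	CcMYB63	Tandem	0.115	0.562	0.204	40.35
CcMYB64	CcMYB80	Segmental	0.281	3.748	0.075	269.24
CcMYB90	CcMYB91	Tandem	0.052	0.263	0.198	18.93
CcMYB90	CcMYB87	Segmental	0.172	3.742	0.046	268.83
CcMYB90	CcMYB89	Segmental	0.156	0.985	0.159	70.74
CcMYB90	CcMYB86	Segmental	0.347	2.739	0.127	196.74
CcMYB90	CcMYB85	Segmental	0.329	3.449	0.096	247.77
CcMYB90	CcMYB83	Segmental	0.359	3.568	0.101	256.29
CcMYB90	CcMYB84	Segmental	0.381	2.282	0.167	163.91
CcMYBC2	CcMYBC1	Segmental	0.158	1.221	0.130	87.75
CcMYBH1	CcMYBH5	Segmental	0.181	0.534	0.339	38.39
CcMYBR10	CcMYBR11	Tandem	0.046	0.070	0.655	4.99
CcMYR1	CcMYR2	Segmental	0.167	0.520	0.322	37.35
CcPHR10	CcPHR3-2	Tandem	0.196	0.218	0.899	15.69
CcPHR10	CcPHR4	Tandem	0.172	0.264	0.651	18.96
CcPHR10	CcPHR3-1	Tandem	0.240	0.333	0.721	23.94
CcPHR3-1	CcPHR3-2	Tandem	0.052	0.098	0.528	7.03
CcPHR4	CcPHR3-2	Tandem	NA	NA	NA	NA
CcPHR4	CcPHR3-1	Tandem	0.044	0.107	0.415	7.69
CcPHR4	CcPHR5	Tandem	0.085	0.138	0.619	9.89
CcRAD3	CcRAD6	Segmental	0.144	1.636	0.088	117.50
CcRAD3	CcRAD4	Segmental	0.288	3.758	0.077	269.94
CcRAD3	CcRAD5	Segmental	0.213	2.091	0.102	150.25
CcRAD4	CcRAD6	Segmental	0.188	3.621	0.052	260.12
CcRAD4	CcRAD3	Segmental	0.288	3.758	0.077	269.94
CcRAD5	CcRAD6	Tandem	0.078	0.143	0.549	10.25
CcRAD5	CcRAD3	Segmental	0.213	2.091	0.102	150.25
CcRL1	CcRAD2	Tandem	0.418	2.159	0.194	155.10
CcRL2	CcRL1	Segmental	0.210	1.744	0.120	125.30
CcRL3	CcRAD2	Segmental	0.225	4.043	0.056	290.42
CcSRM1	CcSRM2	Segmental	0.464	1.053	0.440	75.63
CcTRF3	CcTRF4	Segmental	0.066	0.107	0.617	7.70
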