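region	abbreviation	r_original	p_original	r_corrected	p_corrected	z_difference	p_z
Banks of superior temporal sulcus	BSTS	0.26	1.2e-2	0.42	3.2e-5	1.21	1.9e-1
Caudal anterior cingulate	CACG	0.16	1.1e-1	0.38	2.0e-4	1.64	1.0e-1
Caudal middle frontal gyrus	CMFG	0.13	1.7e-1	0.41	4.6e-5	2.11	4.3e-2
Cuneus	CU	0.16	1.2e-1	0.46	2.7e-6	2.38	2.3e-2
Entorhinal cortex	EC	0.07	3.2e-1	0.59	2.8e-10	4.22	5.4e-5
Fusiform gyrus	FG	0.13	1.8e-1	0.58	7.4e-10	3.70	4.3e-4
Inferior parietal gyrus	IPG	0.24	2.0e-2	0.36	3.4e-4	0.95	2.5e-1
Inferior temporal gyrus	ITG	0.14	1.5e-1	0.49	5.2e-7	2.74	9.3e-3
Isthmus cingulate gyrus	ICG	0.17	8.8e-2	0.43	1.7e-5	1.97	5.7e-2
Lateral occipital gyrus	LOG	0.16	1.0e-1	0.45	5.2e-6	2.23	3.3e-2
Lateral orbito-frontal gyrus	LOFG	0.09	2.7e-1	0.49	5.8e-7	3.10	3.3e-3
Lingual gyrus	LG	0.11	2.1e-1	0.51	1.4e-7	3.13	3.0e-3
Medial orbito-frontal gyrus	MOFG	0.09	2.6e-1	0.42	2.3e-5	2.50	1.8e-2
Middle temporal gyrus	MTG	0.16	1.1e-1	0.34	8.5e-4	1.35	1.6e-1
Para hippocampal gyrus	PHIG	0.09	2.6e-1	0.55	5.2e-9	3.70	4.3e-4
Para central gyrus	PaCG	0.07	3.0e-1	0.49	4.7e-7	3.23	2.2e-3
Pars-opercularis	POP	0.19	6.8e-2	0.38	2.1e-4	1.43	1.4e-1
Pars-orbitalis	POR	0.10	2.3e-1	0.33	1.1e-3	1.70	9.5e-2
Pars-triangularis	PTR	0.12	2.0e-1	0.29	4.7e-3	1.28	1.8e-1
Pericalcarine	PCAL	0.16	1.2e-1	0.48	9.1e-7	2.55	1.5e-2
Postcentral gyrus	PoCG	0.09	2.6e-1	0.42	2.3e-5	2.51	1.7e-2
Posterior cingulate gyrus	PCG	0.18	8.0e-2	0.39	1.0e-4	1.62	1.0e-1
Precentral gyrus	PrCG	0.09	2.7e-1	0.46	2.9e-6	2.86	6.7e-3
Precuneus	PCU	0.18	7.7e-2	0.42	2.6e-5	1.84	7.0e-2
Rostral anterior cingulate gyrus	RACG	0.17	9.6e-2	0.36	3.9e-4	1.45	1.4e-1
Rostral middle frontal gyrus	RMFG	0.09	2.7e-1	0.31	2.6e-3	1.62	1.1e-1
Superior frontal gyrus	SFG	0.09	2.8e-1	0.45	5.0e-6	2.79	8.1e-3
Superior parietal gyrus	SPG	0.17	9.8e-2	0.49	6.6e-7	2.51	1.7e-2
Superior temporal gyrus	STG	0.15	1.3e-1	0.35	5.7e-4	1.50	1.3e-1
Supramarginal gyrus	SMG	0.23	2.8e-2	0.40	7.4e-5	1.33	1.7e-1
Frontal pole	FP	0.12	1.9e-1	0.53	3.6e-8	3.23	2.1e-3
Temporal pole	TP	0.15	1.4e-1	0.50	2.5e-7	2.79	8.0e-3
Transverse temporal gyrus	TTG	0.18	7.2e-2	0.27	8.7e-3	0.65	3.2e-1
Insula	IN	0.18	7.7e-2	0.42	2.3e-5	1.87	7.0e-2
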