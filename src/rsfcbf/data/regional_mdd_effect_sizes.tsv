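region	abbreviation	d_rsfmri	p_rsfmri	d_spect	p_spect
Banks of superior temporal sulcus	BSTS	-0.28	1e-16	-0.27	0.01
Caudal anterior cingulate	CACG	-0.34	1e-16	-0.55	6e-7
Caudal middle frontal gyrus	CMFG	-0.10	4e-5	-0.29	0.009
Cuneus	CU	-0.24	1e-16	-0.33	0.002
Entorhinal cortex	EC	-0.13	3e-8	-0.03	0.4
Fusiform gyrus	FG	-0.27	1e-16	-0.46	3e-5
Inferior parietal gyrus	IPG	-0.20	1e-16	-0.45	3e-5
Inferior temporal gyrus	ITG	-0.25	1e-16	-0.27	0.02
Isthmus cingulate gyrus	ICG	-0.39	1e-16	-0.41	2e-4
Lateral occipital gyrus	LOG	-0.24	1e-16	-0.37	1e-3
Lateral orbito-frontal gyrus	LOFG	-0.30	1e-16	-0.70	2e-10
Lingual gyrus	LG	-0.19	1e-16	-0.18	0.09
Medial orbito-frontal gyrus	MOFG	-0.29	1e-16	-0.58	1e-7
Middle temporal gyrus	MTG	-0.32	1e-16	-0.64	6e-9
Para hippocampal gyrus	PHIG	-0.28	1e-16	-0.28	0.01
Para central gyrus	PaCG	-0.25	1e-16	-0.41	2e-4
Pars-opercularis	POP	-0.37	1e-16	-0.67	1e-9
Pars-orbitalis	POR	-0.31	1e-16	-0.27	0.02
Pars-triangularis	PTR	-0.35	1e-16	-0.69	4e-10
Pericalcarine	PCAL	-0.10	1e-5	-0.03	0.4
Postcentral gyrus	PoCG	-0.25	1e-16	-0.32	0.004
Posterior cingulate gyrus	PCG	-0.17	1e-14	0.19	0.08
Precentral gyrus	PrCG	-0.31	1e-16	-0.26	0.02
Precuneus	PCU	-0.24	1e-16	-0.37	8e-4
Rostral anterior cingulate gyrus	RACG	-0.03	0.2	-0.005	0.4
Rostral middle frontal gyrus	RMFG	-0.30	1e-16	-0.56	3e-7
Superior frontal gyrus	SFG	-0.38	1e-16	-0.42	2e-4
Superior parietal gyrus	SPG	-0.17	3e-14	-0.29	0.008
Superior temporal gyrus	STG	-0.31	1e-16	-0.67	1e-9
Supramarginal gyrus	SMG	-0.25	1e-16	-0.51	2e-6
Frontal pole	FP	-0.06	0.008	0.06	0.3
Temporal pole	TP	-0.24	1e-16	-0.46	3e-5
Transverse temporal gyrus	TTG	-0.14	1e-8	-0.36	1e-3
Insula	IN	-0.34	1e-16	-0.39	4e-4
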