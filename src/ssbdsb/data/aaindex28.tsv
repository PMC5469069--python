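accession	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y	description
CHOP780202	0.83	1.19	0.54	0.37	1.38	0.75	0.87	1.6	0.74	1.3	1.05	0.89	0.55	1.1	0.93	0.75	1.19	1.7	1.37	1.47	Normalized frequency of beta-sheet (Chou-Fasman, 1978b)
GEIM800106	0.86	0.91	0.66	0.37	1.34	0.86	1.07	1.17	1.01	1.28	1.15	0.6	0.61	1.11	1.15	0.91	1.14	1.31	1.13	1.37	Beta-strand indices for beta-proteins (Geisow-Roberts, 1980)
PALJ810107	1.08	1.22	0.86	1.09	0.96	0.85	1.02	0.98	1.01	1.04	1.11	1.05	0.91	0.95	0.93	0.95	1.15	1.03	1.17	0.8	Normalized frequency of alpha-helix in all-alpha class (Palau et al., 1981)
ZIMJ680104	6	5.05	2.77	3.22	5.48	5.97	7.59	6.02	9.74	5.98	5.74	5.41	6.3	5.65	10.76	5.68	5.66	5.96	5.89	5.66	Isoelectric point (Zimmerman et al., 1968)
CIDH920103	0.36	0.7	-1.09	-0.83	1.01	-0.82	0.16	2.17	-0.56	1.18	1.21	-0.9	-0.06	-1.05	-0.52	-0.6	-1.2	1.21	1.31	1.05	Normalized hydrophobicity scales for alpha+beta-proteins (Cid et al., 1992)
KANM800102	0.81	1.17	0.71	0.53	1.2	0.88	0.92	1.48	0.77	1.24	1.05	0.62	0.61	0.98	0.85	0.92	1.18	1.66	1.18	1.23	Average relative probability of beta-sheet (Kanehisa-Tsong, 1980)
QIAN880123	-0.44	0.13	-0.2	-0.28	-0.13	0.08	0.09	-0.04	-0.33	-0.12	-0.21	0.05	-0.48	-0.58	-0.13	0.27	0.47	0.06	-0.22	-0.11	Weights for beta-sheet at the window position of 3 (Qian-Sejnowski, 1988)
AURR980120	0.71	0.65	1.43	1.19	0.95	1.07	1.13	1.05	1.1	0.84	0.8	0.95	1.7	0.87	1.09	0.65	0.086	1.12	1.25	0.85	Normalized positional residue frequency at helix termini C4' (Aurora-Rose, 1998)
CIDH920105	0.02	0.77	-1.04	-1.14	1.35	-0.8	0.26	1.81	-0.41	1.14	1	-0.77	-0.09	-1.1	-0.42	-0.97	-0.77	1.13	1.71	1.11	Normalized average hydrophobicity scales (Cid et al., 1992)
KLEP840101	0	0	-1	-1	0	0	0	0	1	0	0	0	0	0	1	0	0	0	0	0	Net charge (Klein et al., 1984)
RACS770103	1.16	0.5	2.66	2.4	0.43	1.63	0.86	0.57	3.9	0.51	0.4	1.97	2.04	3.87	1.72	1.61	1.48	0.59	0.75	1.72	Side chain orientational preference (Rackovsky-Scheraga, 1977)
MUNV940103	1.08	0.733	1.266	1.085	0.685	1.104	0.906	0.583	1.026	0.789	0.812	1.197	1.412	1.05	0.976	0.987	0.784	0.546	0.755	0.665	Free energy in beta-strand conformation (Munoz-Serrano, 1994)
FAUJ880109	0	0	1	1	0	0	1	0	2	0	0	2	0	2	4	1	1	0	1	1	Number of hydrogen bond donors (Fauchere et al., 1988)
KRIW710101	4.6	-1	5.7	5.6	3.2	7.6	4.5	2.6	7.9	3.25	1.4	5.9	7	6.1	6.5	5.25	4.8	3.4	4	4.35	Side chain interaction parameter (Krigbaum-Rubin, 1971)
RADA880108	-0.06	1.36	-0.8	-0.77	1.27	-0.41	0.49	1.31	-1.18	1.21	1.27	-0.48	0	-0.73	-0.84	-0.5	-0.27	1.09	0.88	0.33	Mean polarity (Radzicka-Wolfenden, 1988)
NADH010104	32	182	-29	-74	132	-22	-25	106	-124	104	82	-73	-82	-95	-95	-34	20	113	118	44	Hydropathy scale based on self-information values in the two-state model (20% accessibility) (Naderi-Manesh et al., 2001)
FAUJ880111	0	0	0	0	0	0	1	0	1	0	0	0	0	0	1	0	0	0	0	0	Positive charge (Fauchere et al., 1988)
LIFS790101	0.92	1.16	0.48	0.61	1.25	0.61	0.93	1.81	0.7	1.3	1.19	0.6	0.4	0.95	0.93	0.82	1.12	1.81	1.54	1.53	Conformational preference for all beta-strands (Lifson-Sander, 1979)
ROSM880102	-0.67	-2	1.57	1.78	-3.24	0	1.09	-3.02	2.46	-3.02	-1.67	2.27	-1.75	2.12	3.89	0.1	-0.42	-2.18	-2.86	0.98	Side chain hydropathy, corrected for solvation (Roseman, 1988)
NADH010106	5	224	45	-8	117	-47	-50	83	-38	82	83	-77	-103	-67	-57	-41	79	117	130	27	Hydropathy scale based on self-information values in the two-state model (36% accessibility) (Naderi-Manesh et al., 2001)
FINA910104	1	1	0.7	0.7	1	1.5	1	1	1.7	1	1	1	0.1	1	1.7	1	1	1	1	1	Helix termination parameter at posision j+1 (Finkelstein et al., 1991)
MEEJ800101	0.5	-6.8	-8.2	-16.9	13.2	0	-3.5	13.9	0.1	8.8	4.8	0.8	6.1	-4.8	0.8	1.2	2.7	2.7	14.9	6.1	Retention coefficient in HPLC, pH7.4 (Meek, 1980)
SWER830101	-0.4	0.17	-1.31	-1.22	1.92	-0.67	-0.64	1.25	-0.67	1.22	1.02	-0.92	-0.49	-0.91	-0.59	-0.55	-0.28	0.91	0.5	1.67	Optimal matching hydrophobicity (Sweet-Eisenberg, 1983)
GUYH850105	-0.27	-0.23	0.5	0.33	-0.55	-0.22	0.37	-0.8	1.17	-0.44	-0.31	0.61	0.36	1	2	0.17	0.18	-0.65	0.05	0.48	Apparent partition energies calculated from Chothia index (Guy, 1985)
GEIM800104	1.19	0.95	1.07	1.64	1.02	0.6	1.03	1.12	1.27	1.18	1.49	0.94	0.68	1.32	1	0.81	0.85	0.74	1.18	0.77	Alpha-helix indices for alpha/beta-proteins (Geisow-Roberts, 1980)
OOBM770102	-1.404	-1.365	-1.162	-1.163	-1.135	-1.364	-1.215	-1.189	-1.074	-1.315	-1.303	-1.178	-1.236	-1.116	-0.921	-1.297	-1.252	-1.254	-1.03	-1.03	Short and medium range non-bonded energy per atom (Oobatake-Ooi, 1977)
ZIMJ680102	11.5	13.46	11.68	13.57	19.8	3.4	13.69	21.4	15.71	21.4	16.25	12.82	17.43	14.45	14.28	9.47	15.77	21.57	21.67	18.03	Bulkiness (Zimmerman et al., 1968)
MIYS990104	-0.04	-0.38	0.19	0.23	-0.38	0.09	-0.04	-0.34	0.33	-0.37	-0.3	0.13	0.19	0.14	0.07	0.12	0.03	-0.29	-0.33	-0.29	Optimized relative partition energies - method C (Miyazawa-Jernigan, 1999)
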