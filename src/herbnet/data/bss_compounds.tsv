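id	name	herb	ob	caco2	dl
C1	()-alpha-Terpineol	DG	46.3	1.28	0.03
C2	()-Aromadendrene	CG	55.74	1.81	0.1
C3	()-Terpinen-4-ol	CG	81.41	1.36	0.03
C4	(+)-alpha-Funebrene	CG	52.87	1.79	0.1
C5	(+)-Ledol	DG	16.96	1.43	0.12
C6	(1R,5R,7S)-4,7-Dimethyl-7-(4-methylpent-3-enyl)bicyclo[3.1.1]hept-3-ene	CG	16.23	1.86	0.09
C7	(1S,4aR,8aR)-1-Isopropyl-7-methyl-4-methylene-2,3,4a,5,6,8a-hexahydro-1H-naphthalene	DG	19.8	1.86	0.08
C8	(1S,4E,8E,10R)-4,8,11,11-tetramethylbicyclo[8.1.0]undeca-4,8-diene	CG	21.69	1.86	0.08
C9	(3E)-3-butylidene-7-hydroxy-2-benzofuran-1-one	DG	42.17	1.03	0.08
C10	(L)-alpha-Terpineol	CG	48.8	1.39	0.03
C11	(R)-Linalool	CG	39.8	1.33	0.02
C12	(Z)-Ligustilide	CG	53.72	1.3	0.07
C13	1-Acetyl-beta-carboline	CG	67.12	1.18	0.13
C14	1-beta-Ethylacrylate-7-aldehyde-beta-carboline	CG	28.53	0.45	0.31
C15	1H-Cycloprop(e)azulen-7-ol, decahydro-1,1,7-trimethyl-4-methylene-, (1aR-(1aalpha,4aalpha,7beta,7abeta,7balpha))-	CG	82.33	1.37	0.12
C16	1-Terpineol	CG	49.83	1.24	0.03
C17	2,6-Di(phenyl)thiopyran-4-thione	DG	69.13	1.74	0.15
C18	2-[(2S,5S,6S)-6,10-Dimethylspiro[4.5]dec-9-en-2-yl]propan-2-ol	CG	37.62	1.44	0.09
C19	3-Butylidene-7-hydroxyphthalide	CG;DG	62.68	1	0.08
C20	4,7-Dihydroxy-3-butylphthalide	CG	106.09	0.69	0.1
C21	49070_FLUKA	CG	85.51	1.29	0.12
C22	4-Hydroxy-3-butylphthalide	CG	70.31	0.9	0.08
C23	58870_FLUKA	CG	49.01	1.82	0.1
C24	Adenine	CG;DG	62.81	-0.3	0.03
C25	ADO	CG	15.98	-1.56	0.18
C26	alpha-Cubebene	CG	16.73	1.83	0.11
C27	alpha-Selinene	CG	31.81	1.82	0.1
C28	Aromadendrene oxide 2	CG	65.1	1.56	0.14
C29	BdPh	CG;DG	42.44	1.32	0.07
C30	beta-Chamigrene	DG	31.99	1.82	0.08
C31	beta-Selinene	CG;DG	24.39	1.83	0.08
C32	beta-Cubebene	CG	32.16	1.82	0.11
C33	Cadinene	DG	17.12	1.88	0.08
C34	Caffeic acid	CG	25.76	0.21	0.05
C35	Carotol	CG	149.03	1.46	0.09
C36	Cedrene	CG	51.14	1.82	0.11
C37	Chuanxiongol	CG	22.19	0.94	0.1
C38	cis-Thujopsene	DG	56.43	1.84	0.12
C39	Coniferyl ferulate	DG	4.54	0.71	0.39
C40	Crysophanol	CG	18.64	0.62	0.21
C41	FA	CG	68.96	-1.5	0.71
C42	Ferulic acid (CIS)	DG	54.97	0.53	0.06
C43	InChI=1/C15H24/c1-10-7-8-15-9-12(10)14(3,4)13(15)6-5-11(15)2/h7,11-13H,5-6,8-9H2,1-4H	DG	55.56	1.79	0.1
C44	L-Bornyl acetate	CG	65.52	1.29	0.08
C45	Methyl palmitate	CG	18.09	1.37	0.12
C46	Myricanone	CG	40.6	0.67	0.51
C47	Nicotinic acid	DG	47.65	0.34	0.02
C48	Oleic acid	CG	33.13	1.17	0.14
C49	Palmitic acid	CG;DG	19.3	1.09	0.1
C50	Perlolyrine	CG	65.95	0.88	0.27
C51	PLO	CG	14.07	0.69	0.43
C52	Scopoletol	DG	27.77	0.71	0.08
C53	Senkyunolide A	CG	26.56	1.3	0.07
C54	Senkyunolide G	CG	39.52	0.63	0.08
C55	Senkyunolide-C	CG;DG	46.8	0.87	0.08
C56	Senkyunolide-D	CG;DG	79.13	0.12	0.1
C57	Senkyunolide-E	CG;DG	34.4	0.55	0.08
C58	Senkyunolide-K	CG	61.75	0.52	0.08
C59	Sinapic acid	CG	64.15	0.48	0.08
C60	Sphingomyelin	DG	0.31	-0.46	0.51
C61	Stearic acid	CG	17.83	1.15	0.14
C62	Stigmasterol	DG	43.83	1.44	0.76
C63	Succinic acid	DG	29.62	-0.44	0.01
C64	Sucrose	CG	7.17	-2.89	0.23
C65	Wallichilide	CG	42.31	0.82	0.71
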