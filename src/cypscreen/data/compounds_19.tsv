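name	smiles	mw_published	hbd_published	hba_published	logp_published	logs_published	psa_published	rotb_published	cyp2d6_evidence
(-)-Cytisine	O=c1cccc2n1C[C@@H]1CNC[C@H]2C1	190	1	5	0.7	-0.8	45	0	inhibition
4-Hydroxyisoleucine	C[C@@H]([C@H](O)C)[C@H](N)C(=O)O	147	4	5	-2.5	0.0	91	5	unknown
5-Isopropyl-2-methylphenol	CC(C)c1ccc(C)c(O)c1	150	1	1	3.3	-2.3	21	2	unknown
Auraptenol	COc1ccc2ccc(=O)oc2c1CC(O)C(C)=C	260	1	5	2.2	-2.6	61	5	unknown
Chelidonic acid	O=C(O)c1cc(=O)cc(C(=O)O)o1	184	2	7	-0.6	-1.0	140	2	unknown
D-(-)-Synephrine	CNC[C@@H](O)c1ccc(O)cc1	167	3	4	0.2	-0.3	58	5	unknown
Honokiol	C=CCc1ccc(O)c(-c2cc(CC=C)ccc2O)c1	266	2	2	5.0	-4.3	42	7	inhibition
Isorhynchophylline	CC[C@H]1CN2CC[C@@]3(c4ccccc4NC3=O)[C@@H]2C[C@@H]1/C(=C\OC)C(=O)OC	385	1	8	2.6	-4.0	85	4	inhibition
L-Theanine	CCNC(=O)CC[C@H](N)C(=O)O	174	4	6	-3.0	0.2	111	6	no_inhibition
Magnolol	C=CCc1ccc(O)c(-c2cc(CC=C)ccc2O)c1	266	2	2	5.0	-4.2	42	7	inhibition
Naringenin	O=C1C[C@H](c2ccc(O)cc2)Oc2cc(O)cc(O)c12	272	2	4	1.6	-3.4	100	3	no_inhibition
Orcinol	Cc1cc(O)cc(O)c1	124	2	2	0.8	0.1	45	2	no_inhibition
Piperine	O=C(/C=C/C=C/c1ccc2OCOc2c1)N1CCCCC1	285	0	5	3.3	-3.5	48	5	inhibition
Protopine	CN1CCc2cc3c(cc2C(=O)Cc2ccc4c(c2C1)OCO4)OCO3	353	0	7	1.7	-1.1	60	0	inhibition
Psoralidin	CC(C)=CCc1cc2c(cc1O)oc1c2c(=O)oc2cc(O)ccc12	336	2	5	3.0	-5.0	92	4	no_inhibition
Salvigenin	COc1ccc(-c2cc(=O)c3c(O)c(OC)c(OC)cc3o2)cc1	328	0	5	3.3	-4.1	77	4	unknown
Scopoletin	COc1cc2ccc(=O)oc2cc1O	192	1	4	0.8	-1.7	71	2	unknown
Trans-methylisoeugenol	COc1ccc(/C=C/C)cc1OC	178	0	2	2.8	-3.7	16	3	unknown
Cannabidiol (CBD)	CCCCCc1cc(O)c([C@@H]2C=C(C)CC[C@H]2C(=C)C)c(O)c1	315	2	2	5.3	-6.0	39	7	inhibition
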