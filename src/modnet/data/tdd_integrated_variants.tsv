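gene_symbol	giant_component	hgvsc	hgvsp	existing_variation	allele_frequency	cadd_phred	pli	status	subject1	subject2
ACAN	2	c.5069G>A	p.Gly1690Glu	COSV61356763		18.91	1		het	het
ALDH1A2	2	c.1042G>A	p.Val348Ile	rs4646626	0.458	15.99	0.17	down	het	het
APOA2	1			rs3813628	0.289	17.98	0.35		het
APOB	1-2	c.8216C>T	p.Pro2739Leu	rs676210	0.230	27.5	0		hom
APOB	1-2	c.1853C>T	p.Ala618Val	rs679899	0.401	26.7	0		hom	het
APOB	1-2	c.293C>T	p.Thr98Ile	rs1367117	0.242	21.3	0			het
ARPC5	1-2	c.91G>A	p.Gly31Ser	rs371421898	1.31e-5	21.4		up	het	het
ARPC5	1-2	c.-111T>C		rs2767305	0.527	18.88		up	het
ASCC3	1-2	c.436C>T	p.Leu146Phe	rs9390698	0.346	16.06	0	up		het
ASCC3	1-2	c.5984C>G	p.Ser1995Cys	rs240780	0.682	15.46	0	up	hom	hom
ASCC3	1-2	c.2080-24T>G		rs9403997	0.427	15.05	0	up		het
BDNF	1-2	c.-21-15778G>T		rs10835210	0.330	16.7	1	up	het	het
BMP4	2	c.-7-39A>G		rs2761880	0.836	16.86	1	down	hom	hom
CDKN1B	2			rs71064312	0.425	17.33	0.24		het	het
CDKN1B	2	c.326T>G	p.Val109Gly	rs2066827	0.370	16.88	0.24		het	hom
CHD3	1-2	c.100+209C>T				22.2	1	down	het
CHD3	1-2	c.100+47G>C		rs2279620	0.106	15.69	1	down		het
CYBA	1-2	c.214T>C	p.Tyr72His	rs4673	0.653	21.3	0	up	hom	hom
DNM1	1-2	c.2535-1654G>A		rs2267958	0.385	21.9	1	down	het	het
DOCK2	2	c.321+87C>T		rs12656761	0.199	22.4	1	up	het	het
DOCK3	1-2	c.1918-3T>C		rs1480361	0.991	15.58	1	up	hom	hom
EP300	2	c.*13_*15del		rs35508493	0.246	15.8	1			het
EVC	2	c.1727G>A	p.Arg576Gln	rs1383180	0.321	25.4	0	down	het	het
EVC	2	c.772T>C	p.Tyr258His	rs6414624	0.729	17.5	0	down	hom	hom
EVC	2	c.969T>C	p.Asn323%3D	rs4688963	0.412	16.14	0	down	hom	hom
EVC	2	c.221A>C	p.Gln74Pro	rs2291157	0.083	15.84	0	down	het	het
FBLN1	2	c.422A>G	p.Gln141Arg	rs136730	0.999	16.38	0.95	down	hom	hom
FOXF1	2			rs77626209	0.677	16.1	0.43	down	hom	hom
GLI1	2			rs512490	0.887	16.87	0		hom	hom
GRIA4	1	c.2295-5718G>A		rs632549	0.999	16.05	16.1	down	hom	hom
GRIA4	1	c.1269+1231_1269+1232del		rs60005308	0.009	15.95	16.1	down	het
GRIA4	1	c.2544+250C>T		rs593130	0.647	15.39	16.1	down		hom
GRIN2D	1	c.*132G>T		rs8111684	0.623	18.63		down	hom
HGF	1-2	c.1541+159T>G		rs2074725	0.747	21	1		hom	hom
JPH2	2	c.1186G>A	p.Ala396Thr	rs3810510	0.201	21.3	0	up	het	het
KCNH2	2	c.2690A>C	p.Lys897Thr	rs1805123	0.210	21.7	0.07		het
KCNH2	2	c.-43_-39dup		rs747534042	1.865e-4	21	0.07			het
KCNH2	2	c.77-134dup		rs5888422	1.000	16.32	0.07		hom	hom
LAMB1	2	c.2441G>T	p.Gly814Val	rs556203005	1.971e-5	27.2	0		het	het
LDHA	1	c.439G>T	p.Ala147Ser	rs116841148	0.001	23.8	0.77	up	het
LIPC	1-2	c.1068C>A	p.Phe356Leu	rs3829462	0.946	18.28	0	down	hom	hom
LTBP4	2	c.4298A>T	p.Tyr1433Phe	rs35809725	0.009	22.6	0	down	het	het
LTBP4	2	c.3221C>T	p.Thr1074Met	rs10880	0.392	18.86	0	down	het	het
LYN	2	c.-82G>A		rs1050855	0.505	16.76	1	up		het
MDM2	1	c.*1982G>A				21.5	1	up	het
MDM2	1	c.-94A>G		rs937283	0.363	17.85	1	up	het
MECOM	1-2	c.376-2930A>T		rs1420476	0.963	15.34	1	up	hom	hom
MSX2	1-2	c.386T>C	p.Met129Thr	rs4242182	0.779	21.7	0.01	down	hom	hom
MYO6	1	c.2077+96T>A		rs9443195	0.338	15.86	0.97	up	hom	het
NGF	1	c.104C>T	p.Ala35Val	rs6330	0.356	21.8	0.77		het
NTN1	1	c.*30_*33del		rs762914852	2.56e-4	16.28	1	down	het
PDGFRB	1-2	c.946G>A	p.Val316Met	rs41287112	0.003	17.86	0.94	down	het	het
PIK3R1	1-2	c.917-3329A>G		rs1862162	0.222	15.88	1		het	het
PKD2	2	c.83G>C	p.Arg28Pro	rs1805044	0.234	20.4	0	up	het	het
PLOD2	2	c.338+4G>A		rs4681297	0.777	16.55	0	up	hom	het
PRKACA	2	c.47-270T>C		rs35374974	0.213	15.78	1			het
PSMC3IP	2	c.338-15C>G		rs2292752	0.574	17.58	0	up	het	hom
PTPN22	1-2	c.1858T>C	p.Trp620Arg	rs2476601	0.934	15.54	0	up	hom	hom
RET	1-2	c.3187+198T>A		rs2075913	0.757	22.1	1		het	het
RET	1-2	c.2712C>G	p.Ser904%3D	rs1800863	0.173	17.21	1			het
RET	1-2	c.73+53G>A		rs12267460	0.375	16.18	1		het	het
RET	1-2	c.3187+47T>C		rs2075912	0.831	15.58	1		hom	hom
ROR2	2	c.2455G>A	p.Val819Ile	rs10761129	0.715	15.69	0.35	down		het
SPINT2	1-2	c.337+42A>G		rs8104823	0.135	15.15	0	up	het	het
TCF12	1-2	c.222+8793G>A		rs2951904	0.570	17.32	0.02		het	het
TIAM1	1-2	c.740G>T	p.Gly247Val	rs2070417	0.116	23.4	0.99	up	hom	het
TIAM1	1-2	c.739G>A	p.Gly247Arg	rs2070418	0.116	19.54	0.99	up	hom	het
TNC	2	c.5341G>A	p.Ala1781Thr	rs2274750	0.056	25.8	0	down		het
TNC	2	c.2049G>A	p.Glu683%3D	rs2274836	0.440	17.7	0	down		het
TNC	2	c.6022G>C	p.Glu2008Gln	rs13321	0.708	17.31	0	down	hom	hom
TNC	2	c.5029A>T	p.Ile1677Leu	rs2104772	0.471	15.25	0	down	het	het
VLDLR	1-2	c.-69A>G		rs12379259	0.811	18.51	0	up	het	het
VLDLR	1-2	c.-56C>T		rs34881325	0.318	17.4	0	up	het
VLDLR	1-2	c.82+7G>A		rs2219143	0.315	16.9	0	up	het
VLDLR	1-2	c.-43_-35del		rs71329437	0.329	16.53	0	up	het
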