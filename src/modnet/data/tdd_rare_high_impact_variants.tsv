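gene_symbol	hgvsc	hgvsp	existing_variation	allele_frequency	cadd_phred	pli	subjects
ACACB	c.2295+1G>A		rs746447307	1.314e-5	33	0	1
ANKRD13B					32	0	1
CLN5	c.525del	p.Trp175Ter	rs587780315	6.57e-6	34	0	2
CUX1	c.3128C>T	p.Ser1043Leu	rs146486358	3.941e-4	33	1	1-2
DDX20	c.1310C>T	p.Pro437Leu	rs199513956	3.88e-4	34	0	1
DDX56	c.1318C>T	p.Gln440Ter			48	0	2
GAL3ST4	c.1357C>T	p.Arg453Cys	rs150667953	4.735e-4	32	0	1-2
GALNT9	c.976G>A	p.Gly326Ser	rs1245240239		32	0	1
GCA	c.556C>T	p.Arg186Ter	rs141572054	0.002	40	0.04	1
GJC2	c.980T>A	p.Leu327Ter	rs891354098	6.765e-6	34	0.46	2
GOLIM4	c.2005C>T	p.Arg669Ter	rs141565580	4.609e-5	35	0	1-2
GRM6	c.1639C>T	p.Arg547Cys	rs182751201	0.003	33	0	2
GXYLT1	c.97G>T	p.Gly33Ter	rs1262821887	0.004	37	0	1-2
KCNJ12	c.236G>C	p.Arg79Pro	rs377320706	9.192e-5	32	1	2
KRT27	c.847-1G>A		rs187944199	0.002	34	0	2
KRT82	c.139C>T	p.Arg47Ter	rs148453926	0.002	39	0	2
LIFR	c.2578C>T	p.Arg860Trp	rs146205670	0.001	32	0	1-2
LIN7B	c.27del	p.Leu10TrpfsTer84			32	0	1
MKNK2	c.758C>T	p.Ser253Leu	rs2016896796		34	0	2
MUC19	c.23324del	p.Gly7775GlufsTer?	rs748533284	8.546e-5	34		2
NLRP14	c.322A>T	p.Lys108Ter	rs76274604	0.005	34	0	1-2
NOC2L			rs367769858	4.604e-5	34	0	2
OBSL1	c.4732C>T	p.Gln1578Ter	rs116131367	0.003	45	0	2
PABPC1	c.1033G>T	p.Glu345Ter	rs142985461	0.002	45	1	1
PAX7	c.644G>A	p.Arg215His	rs200575057	4.731e-4	33	0.98	2
PCDHGA6	c.1331A>G	p.Asp444Gly	rs752900319	6.571e-6	30	0	2
PIEZO1					33	0	1-2
PIK3C2G	c.2627del	p.Ile876ThrfsTer23	rs765216023	1.315e-4	34	0	2
PLIN2	c.214C>G	p.Leu72Val	rs149124591	0.004	34	0	2
POLR2E	c.496C>T	p.Arg166Ter	rs201275503	3.958e-5	48	0	2
PSD2					34	0	2
PSTPIP2	c.642+1G>T				34	0	1
RANBP3	c.313G>A	p.Gly105Arg	rs749355669		31	1	2
SCGN	c.83-1del		rs60502981	0.009	34	0	2
SCYL3	c.1010G>A	p.Arg337Gln	rs143546688	0.002	33	0	1
SLC2A8	c.617C>T	p.Pro206Leu	rs372901354	3.284e-5	30	0	1
SORT1	c.1108+1G>A				34	0.83	2
SPNS1	c.1550G>A	p.Arg517His	rs149610167	0.005	32	0.03	1-2
SPTA1	c.823_827del	p.Glu275HisfsTer14	rs1654503475		35	0	1-2
SPTA1	c.817_820del	p.Val273LeufsTer43	rs1654503795		33	0	1-2
TANGO2	c.262C>T	p.Arg88Ter	rs140115503	5.473e-5	36	0	1-2
TIE1	c.1297G>A	p.Gly433Ser	rs767153303	1.314e-5	32	0	2
TMEM64	c.767C>A	p.Pro256His	rs144669410	1.971e-5	32	0	1-2
TRPM8	c.1423C>T	p.Arg475Cys	rs201940567	5.259e-4	32	0	1-2
ZNF208	c.2266A>T	p.Lys756Ter	rs370724361	1.118e-4	34	0	2
ZNF256	c.856C>T	p.Arg286Ter	rs748369479	6.574e-6	33	0.28	2
ZNF268	c.2482C>T	p.Arg828Ter	rs200561453	0.001	35	0	1
ZNF468	c.766C>T	p.Arg256Ter	rs531943295	4.602e-5	33	0	1
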