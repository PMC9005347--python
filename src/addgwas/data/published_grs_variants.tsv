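# Genome-wide-significant lead variants of the two-stage dementia GWAS used
# to define the default genetic risk score: 39 lead variants in previously
# known loci (SET=known) and 44 in newly identified loci (SET=novel).
# POS is GRCh38; GENE is the nearest protein-coding gene; MAF is the weighted
# average minor-allele frequency across discovery studies; OR is the
# approximate odds ratio with respect to the minor allele.
SET	LOCUS	RSID	CHR	POS	GENE	MINOR	MAJOR	MAF	OR
known	CR1	rs679515	1	207577223	CR1	T	C	0.188	1.13
known	BIN1	rs6733839	2	127135234	BIN1	T	C	0.389	1.17
known	INPP5D	rs10933431	2	233117202	INPP5D	G	C	0.234	0.93
known	CLNK/HS3ST1	rs6846529	4	11023507	CLNK	C	T	0.283	1.07
known	HLA	rs6605556	6	32615322	HLA-DQA1	G	A	0.161	0.91
known	TREM2	rs10947943	6	41036354	UNC5CL	A	G	0.142	0.94
known	TREM2	rs143332484	6	41161469	TREM2	T	C	0.013	1.41
known	TREM2	rs75932628	6	41161514	TREM2	T	C	0.003	2.39
known	TREM2	rs60755019	6	41181270	TREML2	G	A	0.004	1.55
known	CD2AP	rs7767350	6	47517390	CD2AP	T	C	0.271	1.08
known	NME8	rs6966331	7	37844191	EPDR1	T	C	0.349	0.96
known	ZCWPW1/NYAP1	rs7384878	7	100334426	SPDYE3	C	T	0.310	0.92
known	EPHA1	rs11771145	7	143413669	EPHA1	A	G	0.348	0.95
known	PTK2B	rs73223431	8	27362470	PTK2B	T	C	0.369	1.07
known	CLU	rs11787077	8	27607795	CLU	T	C	0.392	0.91
known	ECHDC3	rs7912495	10	11676714	USP6NL	G	A	0.462	1.06
known	CELF1/SPI1	rs10437655	11	47370397	SPI1	A	G	0.399	1.06
known	MS4A	rs1582763	11	60254475	MS4A4A	A	G	0.371	0.91
known	PICALM	rs3851179	11	86157598	EED	T	C	0.358	0.90
known	SORL1	rs74685827	11	121482368	SORL1	G	T	0.019	1.19
known	SORL1	rs11218343	11	121564878	SORL1	C	T	0.039	0.84
known	FERMT2	rs17125924	14	52924962	FERMT2	G	A	0.089	1.10
known	SLC24A4/RIN3	rs7401792	14	92464917	SLC24A4	G	A	0.371	1.04
known	SLC24A4/RIN3	rs12590654	14	92472511	SLC24A4	A	G	0.328	0.93
known	SPPL2A	rs8025980	15	50701814	SPPL2A	G	A	0.345	0.96
known	ADAM10	rs602602	15	58764824	MINDY2	A	T	0.280	0.94
known	APH1B	rs117618017	15	63277703	APH1B	T	C	0.144	1.11
known	KAT8	rs889555	16	31111250	BCKDK	T	C	0.281	0.95
known	IL34	rs4985556	16	70660097	IL34	A	C	0.115	1.07
known	PLCG2	rs12446759	16	81739398	PLCG2	G	A	0.403	0.95
known	PLCG2	rs72824905	16	81908423	PLCG2	G	C	0.008	0.74
known	SCIMP/RABEP1	rs7225151	17	5233752	SCIMP	A	G	0.124	1.08
known	MAPT	rs199515	17	46779275	WNT3	G	C	0.219	0.94
known	ABI3	rs616338	17	49219935	ABI3	T	C	0.012	1.32
known	TSPOAP1	rs2526377	17	58332680	TSPOAP1	G	A	0.445	0.95
known	ACE	rs4277405	17	63471557	ACE	C	T	0.384	0.94
known	ABCA7	rs12151021	19	1050875	ABCA7	A	G	0.336	1.10
known	CASS4	rs6014724	20	56423488	CASS4	G	A	0.090	0.89
known	ADAMTS1	rs2830489	21	26775872	ADAMTS1	T	C	0.281	0.95
novel	1	rs141749679	1	109345810	SORT1	C	T	0.004	1.38
novel	2	rs72777026	2	9558882	ADAM17	G	A	0.144	1.06
novel	3	rs17020490	2	37304796	PRKD3	C	T	0.145	1.06
novel	4	rs143080277	2	105749599	NCK2	C	T	0.005	1.47
novel	5	rs139643391	2	202878716	WDR12	T	TC	0.131	0.94
novel	6	rs16824536	3	155069722	MME	A	G	0.054	0.92
novel	6	rs61762319	3	155084189	MME	G	A	0.026	1.16
novel	7	rs3822030	4	993555	IDUA	G	T	0.429	0.95
novel	8	rs2245466	4	40197226	RHOH	G	C	0.343	1.05
novel	9	rs112403360	5	14724304	ANKH	A	T	0.073	1.09
novel	10	rs62374257	5	86927378	COX7C	C	T	0.230	1.07
novel	11	rs871269	5	151052827	TNIP1	T	C	0.326	0.96
novel	12	rs113706587	5	180201150	RASGEF1C	A	G	0.110	1.09
novel	13	rs785129	6	114291731	HS3ST5	T	C	0.350	1.04
novel	14	rs6943429	7	7817263	UMAD1	T	C	0.420	1.05
novel	15	rs10952097	7	8204382	ICA1	T	C	0.114	1.07
novel	16	rs13237518	7	12229967	TMEM106B	A	C	0.411	0.96
novel	17	rs1160871	7	28129126	JAZF1	G	GTCTT	0.222	0.95
novel	18	rs76928645	7	54873635	SEC61G	T	C	0.103	0.93
novel	19	rs10657128	8	11844613	CTSB	C	G	0.053	1.09
novel	20	rs34173062	8	144103704	SHARPIN	A	G	0.081	1.13
novel	21	rs1800978	9	104903697	ABCA1	G	C	0.130	1.06
novel	22	rs7068231	10	60025170	ANK3	T	G	0.403	0.95
novel	23	rs6586028	10	80494228	TSPAN14	C	T	0.196	0.93
novel	24	rs6584063	10	96266650	BLNK	G	A	0.043	0.89
novel	25	rs7908662	10	122413396	PLEKHA1	G	A	0.467	0.96
novel	26	rs6489896	12	113281983	TPCN1	C	T	0.076	1.08
novel	27	rs7157106	14	105761758	IGH	A	G	0.360	1.05
novel	27	rs10131280	14	106665591	IGH	A	G	0.133	0.94
novel	28	rs3848143	15	64131307	SNX1	G	A	0.220	1.05
novel	29	rs12592898	15	78936857	CTSH	A	G	0.133	0.94
novel	30	rs1140239	16	30010081	DOC2A	T	C	0.379	0.94
novel	31	rs450674	16	79574511	MAF	C	T	0.373	0.96
novel	32	rs16941239	16	86420604	FOXF1	A	T	0.029	1.13
novel	33	rs56407236	16	90103687	PRDM7	A	G	0.069	1.11
novel	34	rs35048651	17	1728046	WDR81	T	TGAG	0.214	1.06
novel	35	rs2242595	17	18156140	MYO15A	A	G	0.112	0.94
novel	36	rs5848	17	44352876	GRN	T	C	0.289	1.07
novel	37	rs149080927	19	1854254	KLF16	G	GC	0.480	1.05
novel	38	rs9304690	19	49950060	SIGLEC11	T	C	0.240	1.05
novel	39	rs587709	19	54267597	LILRB2	C	T	0.325	1.05
novel	40	rs1358782	20	413334	RBCK1	A	G	0.246	0.95
novel	41	rs6742	20	63743088	SLC2A4RG	T	C	0.221	0.95
novel	42	rs2154481	21	26101558	APP	C	T	0.476	0.95
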