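name	category	strand	letter	st_start	st_end	sa_start	sa_end	sm_start	sm_end	st_size	sa_size	sm_size	st_spacer	sa_spacer	sm_spacer	aa	init	st_term	sa_term	sm_term
tRNA-Phe	tRNA	H	F	1	68	1	68	1	68	68	68	68	0	0	0					
12S-rRNA	rRNA	H		69	1015	69	1014	69	1014	947	946	946	0	0	0					
tRNA-Val	tRNA	H	V	1016	1087	1015	1086	1015	1086	72	72	72	0	0	0					
16S-rRNA	rRNA	H		1088	2779	1087	2778	1087	2778	1692	1692	1692	0	0	0					
tRNA-Leu(UUR)	tRNA	H	L1	2780	2853	2779	2852	2779	2852	74	74	74	0	0	0					
ND1	PCG	H		2854	3828	2853	3827	2853	3827	975	975	975	3	5	3	324	ATG	TAG	TAA	TAA
tRNA-Ile	tRNA	H	I	3832	3903	3833	3902	3831	3902	72	70	72	-2	-1	-2					
tRNA-Gln	tRNA	L	Q	3902	3972	3902	3972	3901	3972	71	71	72	-1	-1	-2					
tRNA-Met	tRNA	H	M	3972	4042	3972	4042	3971	4041	71	71	71	0	0	0					
ND2	PCG	H		4043	5088	4043	5088	4042	5087	1046	1046	1046	0	0	0	348	ATG	TA	TA	TA
tRNA-Trp	tRNA	H	W	5089	5159	5089	5160	5088	5158	71	71	71	1	1	1					
tRNA-Ala	tRNA	L	A	5161	5229	5162	5230	5160	5228	69	69	69	1	1	1					
tRNA-Asn	tRNA	L	N	5231	5303	5232	5304	5230	5302	73	73	73	1	1	0					
OL	origin	H		5305	5341	5306	5342	5303	5340	37	37	38	-3	-3	-4					
tRNA-Cys	tRNA	L	C	5339	5405	5340	5406	5337	5403	67	65	67	2	2	2					
tRNA-Tyr	tRNA	L	Y	5408	5478	5409	5479	5406	5476	69	71	71	1	1	1					
COI	PCG	H		5480	7030	5481	7031	5478	7028	1551	1551	1551	0	0	0	516	GTG	TAA	TAA	TAA
tRNA-Ser(UCN)	tRNA	L	S1	7031	7101	7032	7102	7029	7099	71	69	71	3	3	3					
tRNA-Asp	tRNA	H	D	7105	7177	7106	7178	7103	7175	73	73	73	6	6	6					
COII	PCG	H		7184	7874	7185	7875	7182	7872	691	691	691	0	0	0	230	ATG	T	T	T
tRNA-Lys	tRNA	H	K	7875	7948	7876	7949	7873	7946	74	74	74	1	1	1					
ATP8	PCG	H		7950	8117	7951	8118	7948	8115	168	168	168	-10	-10	-10	55	ATG	TAA	TAA	TAA
ATP6	PCG	H		8108	8790	8109	8791	8106	8788	683	683	683	0	0	0	227	ATG	TA	TA	TA
COIII	PCG	H		8791	9575	8792	9576	8789	9573	785	785	785	0	0	0	261	ATG	TA	TA	TA
tRNA-Gly	tRNA	H	G	9576	9647	9577	9648	9574	9645	72	72	72	0	0	0					
ND3	PCG	H		9648	9996	9649	9997	9646	9994	349	349	349	0	0	0	116	ATG	T	T	T
tRNA-Arg	tRNA	H	R	9997	10065	9998	10066	9995	10063	69	69	69	0	0	0					
ND4L	PCG	H		10066	10362	10067	10363	10064	10360	297	297	297	-7	-7	-7	98	ATG	TAA	TAA	TAA
ND4	PCG	H		10356	11736	10357	11737	10354	11734	1381	1381	1381	0	0	0	460	ATG	T	T	T
tRNA-His	tRNA	H	H	11737	11805	11738	11806	11735	11803	69	69	69	0	0	0					
tRNA-Ser(AGY)	tRNA	H	S2	11806	11873	11807	11874	11804	11871	68	72	68	4	4	4					
tRNA-Leu(CUN)	tRNA	H	L2	11878	11950	11879	11951	11876	11948	73	73	73	0	0	0					
ND5	PCG	H		11951	13789	11952	13790	11949	13787	1839	1839	1839	-4	-4	-4	612	ATG	TAA	TAA	TAA
ND6	PCG	L		13786	14307	13787	14308	13784	14305	522	522	522	0	0	0	173	ATG	TAG	TAG	TAG
tRNA-Glu	tRNA	L	E	14308	14376	14309	14377	14306	14374	69	69	69	6	6	6					
CYTB	PCG	H		14383	15523	14384	15524	14381	15521	1141	1141	1141	0	0	0	380	ATG	T	T	T
tRNA-Thr	tRNA	H	T	15524	15595	15525	15596	15522	15593	72	73	72	-1	-1	-1					
tRNA-Pro	tRNA	L	P	15595	15664	15596	15665	15593	15662	70	70	70	0	0	0					
D-loop	control	H		15665	16910	15666	17056	15663	17580	1246	1391	1918								
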