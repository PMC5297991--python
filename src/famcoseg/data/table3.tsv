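family	gene	chrom	pos	ref	alt	effect	validation	exac	kg
1	CHD5	1	6163696	G	A	DOWNSTREAM	Yes	NC	Absent
1	FAM179A	2	29249757	AC	A	FRAME_SHIFT	Yes	Absent	Absent
1	IL22RA2	6	137465358	C	T	UTR_3_PRIME	Yes	NC	Absent
1	CDK12	17	37689446	C	T	UTR_3_PRIME	Yes	NC	0.003
1	MIRLET7BHG	22	46453973	T	C	INTRON	Yes	NC	Absent
4	ATRAID	2	27439820	A	G	DOWNSTREAM	Yes	NC	Absent
4	RPUSD3	3	9880772	T	C	NON_SYNONYMOUS_CODING=T255A	Yes	0.00015	Absent
4	IFNA21	9	21165905	C	T	UTR_3_PRIME	Yes	NC	Absent
7	LDLRAP1	1	25894878	C	G	DOWNSTREAM	Yes	NC	0.0001
15	UBE4B	1	10190827	C	T	NON_SYNONYMOUS_CODING=R378C	Yes	0.000016	Absent
15	DFFA	1	10527277	G	C	NON_SYNONYMOUS_CODING=S137R	Yes	0.0000082	Absent
15	SLC6A6	3	14528787	A	G	UTR_3_PRIME	Yes	NC	0.00059
15	JADE1	4	129783008	T	A	NON_SYNONYMOUS_CODING=S365R	Yes	0.00001648	Absent
15	SQSTM1	5	179264117	A	G	DOWNSTREAM	Yes	NC	Absent
36	THADA	2	43455302	G	A	DOWNSTREAM	Yes	NC	Absent
36	SETD5	3	9515095	C	A	NON_SYNONYMOUS_CODING=S1026Y	Yes	Absent	Absent
36	PTPRG	3	62063912	G	A	NON_SYNONYMOUS_CODING=A199T	Yes	0.000008341	Absent
36	CYP11B2	8	143993975	C	T	NON_SYNONYMOUS_CODING=E457K	Yes	Absent	Absent
206	THRA	17	38233146	C	T	STOP_GAINED=R26*	Yes	Absent	Absent
206	UBE2G1	17	4173166	G	A	UTR_3_PRIME	Yes	NC	Absent
206	CDC27	17	45197967	A	G	DOWNSTREAM	Yes	NC	0.000199681
385	CAMK2D	4	114374628	T	A	DOWNSTREAM	Yes	NC	0.00259585
385	CHD5	1	6162250	G	GAC	DOWNSTREAM	Yes	NC	0.0071885
483	EDEM1	3	5259973	A	G	UTR_3_PRIME	Yes	NC	Absent
4	TG	8	133925492	C	T	STOP_GAINED=Q1454*	Yes + Control	0.000008248	Absent
7	B4GALT5	20	48250578	T	C	UTR_3_PRIME	Yes + Control	NC	Absent
483	TOM1L2	17	17748047	G	A	DOWNSTREAM	Yes + Control	NC	0.000599042
483	ERAL1	17	27188606	A	C	DOWNSTREAM	Yes + Control	NC	Absent
1	BCLAF1	6	136579552	A	G	DOWNSTREAM	Repeat region	NC	Absent
36	BCLAF1	6	136579558	A	G	DOWNSTREAM	Repeat region	NC	Absent
4	USP6	17	5036210	T	G	NON_SYNONYMOUS_CODING=I67M	Not confirmed	NC	Absent
7	CAAP1	9	26841936	C	A	DOWNSTREAM	Not confirmed	NC	Absent
36	USP22	17	20931986	G	T	NON_SYNONYMOUS_CODING=A126D	Not confirmed	NC	Absent
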