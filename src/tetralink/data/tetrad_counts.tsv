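background	strain	genotype	interval	chromosome	PD	TT	NPD
pch2	AM3724	pch2	HIS4-CEN3	III	254	255	12
pch2	AM3724	pch2	CEN3-MAT	III	265	253	13
pch2	AM3724	pch2	MAT-RAD18	III	168	317	29
pch2	AM3724	pch2	RAD18-HMR	III	282	221	10
pch2	AM3724	pch2	SPO11-SPO13	VIII	180	310	38
pch2	AM3724	pch2	SPO13-THR1	VIII	362	146	3
pch2	AM3724	pch2	THR1-LYS2	VIII	142	301	45
pch2	AM4025	pch2 msh4	HIS4-CEN3	III	161	34	2
pch2	AM4025	pch2 msh4	CEN3-MAT	III	179	22	1
pch2	AM4025	pch2 msh4	MAT-RAD18	III	139	60	2
pch2	AM4025	pch2 msh4	RAD18-HMR	III	149	51	1
pch2	AM4025	pch2 msh4	SPO11-SPO13	VIII	162	35	0
pch2	AM4025	pch2 msh4	SPO13-THR1	VIII	165	23	0
pch2	AM4025	pch2 msh4	THR1-LYS2	VIII	99	84	4
pch2	AM4023	pch2 zip1	HIS4-CEN3	III	78	16	0
pch2	AM4023	pch2 zip1	CEN3-MAT	III	69	27	1
pch2	AM4023	pch2 zip1	MAT-RAD18	III	62	28	2
pch2	AM4023	pch2 zip1	RAD18-HMR	III	75	17	2
pch2	AM4023	pch2 zip1	SPO11-SPO13	VIII	56	40	1
pch2	AM4023	pch2 zip1	SPO13-THR1	VIII	74	14	2
pch2	AM4023	pch2 zip1	THR1-LYS2	VIII	53	36	1
pch2	AM3725	pch2 zip1[D2-163]	HIS4-CEN3	III	265	50	0
pch2	AM3725	pch2 zip1[D2-163]	CEN3-MAT	III	263	57	0
pch2	AM3725	pch2 zip1[D2-163]	MAT-RAD18	III	203	104	5
pch2	AM3725	pch2 zip1[D2-163]	RAD18-HMR	III	258	55	1
pch2	AM3725	pch2 zip1[D2-163]	SPO11-SPO13	VIII	226	82	2
pch2	AM3725	pch2 zip1[D2-163]	SPO13-THR1	VIII	253	31	0
pch2	AM3725	pch2 zip1[D2-163]	THR1-LYS2	VIII	155	121	8
pch2	AM4026	pch2 zip1 msh4	HIS4-CEN3	III	21	2	0
pch2	AM4026	pch2 zip1 msh4	CEN3-MAT	III	17	7	0
pch2	AM4026	pch2 zip1 msh4	MAT-RAD18	III	14	9	1
pch2	AM4026	pch2 zip1 msh4	RAD18-HMR	III	20	5	0
pch2	AM4026	pch2 zip1 msh4	SPO11-SPO13	VIII	11	10	0
pch2	AM4026	pch2 zip1 msh4	SPO13-THR1	VIII	20	2	0
pch2	AM4026	pch2 zip1 msh4	THR1-LYS2	VIII	12	9	1
PCH2	K842	wild type	HIS4-CEN3	III	344	325	6
PCH2	K842	wild type	CEN3-MAT	III	427	250	4
PCH2	K842	wild type	MAT-RAD18	III	255	405	14
PCH2	K842	wild type	RAD18-HMR	III	395	273	6
PCH2	K842	wild type	SPO11-SPO13	VIII	251	401	21
PCH2	K842	wild type	SPO13-THR1	VIII	565	94	1
PCH2	K842	wild type	THR1-LYS2	VIII	296	361	5
PCH2	K852	msh4	HIS4-CEN3	III	373	96	1
PCH2	K852	msh4	CEN3-MAT	III	424	50	1
PCH2	K852	msh4	MAT-RAD18	III	275	183	7
PCH2	K852	msh4	RAD18-HMR	III	351	115	0
PCH2	K852	msh4	SPO11-SPO13	VIII	365	88	3
PCH2	K852	msh4	SPO13-THR1	VIII	423	27	0
PCH2	K852	msh4	THR1-LYS2	VIII	320	129	2
PCH2	AM3684	zip1[D2-20]	HIS4-CEN3	III	463	107	3
PCH2	AM3684	zip1[D2-20]	CEN3-MAT	III	453	123	2
PCH2	AM3684	zip1[D2-20]	MAT-RAD18	III	315	204	15
PCH2	AM3684	zip1[D2-20]	RAD18-HMR	III	346	197	6
PCH2	AM3684	zip1[D2-20]	SPO11-SPO13	VIII	394	143	5
PCH2	AM3684	zip1[D2-20]	SPO13-THR1	VIII	390	88	2
PCH2	AM3684	zip1[D2-20]	THR1-LYS2	VIII	262	203	11
PCH2	K1000	zip1[D2-20] msh4	HIS4-CEN3	III	365	58	3
PCH2	K1000	zip1[D2-20] msh4	CEN3-MAT	III	336	97	3
PCH2	K1000	zip1[D2-20] msh4	MAT-RAD18	III	271	133	10
PCH2	K1000	zip1[D2-20] msh4	RAD18-HMR	III	297	117	2
PCH2	K1000	zip1[D2-20] msh4	SPO11-SPO13	VIII	280	104	5
PCH2	K1000	zip1[D2-20] msh4	SPO13-THR1	VIII	299	68	0
PCH2	K1000	zip1[D2-20] msh4	THR1-LYS2	VIII	194	160	7
PCH2	MP43	zip1[D2-9]	HIS4-CEN3	III	428	149	2
PCH2	MP43	zip1[D2-9]	CEN3-MAT	III	441	140	1
PCH2	MP43	zip1[D2-9]	MAT-RAD18	III	331	241	8
PCH2	MP43	zip1[D2-9]	RAD18-HMR	III	361	222	4
PCH2	MP43	zip1[D2-9]	SPO11-SPO13	VIII	414	156	2
PCH2	MP43	zip1[D2-9]	SPO13-THR1	VIII	526	38	0
PCH2	MP43	zip1[D2-9]	THR1-LYS2	VIII	400	165	2
PCH2	MP46	zip1[D2-9] msh4	HIS4-CEN3	III	389	106	4
PCH2	MP46	zip1[D2-9] msh4	CEN3-MAT	III	396	106	0
PCH2	MP46	zip1[D2-9] msh4	MAT-RAD18	III	299	185	9
PCH2	MP46	zip1[D2-9] msh4	RAD18-HMR	III	354	136	3
PCH2	MP46	zip1[D2-9] msh4	SPO11-SPO13	VIII	364	117	3
PCH2	MP46	zip1[D2-9] msh4	SPO13-THR1	VIII	452	24	0
PCH2	MP46	zip1[D2-9] msh4	THR1-LYS2	VIII	361	109	4
PCH2	SYC107	zip1[D10-14]	HIS4-CEN3	III	411	139	5
PCH2	SYC107	zip1[D10-14]	CEN3-MAT	III	443	119	5
PCH2	SYC107	zip1[D10-14]	MAT-RAD18	III	336	219	5
PCH2	SYC107	zip1[D10-14]	RAD18-HMR	III	365	196	1
PCH2	SYC107	zip1[D10-14]	SPO11-SPO13	VIII	399	149	2
PCH2	SYC149	zip1[D10-14] msh4	HIS4-CEN3	III	267	78	4
PCH2	SYC149	zip1[D10-14] msh4	CEN3-MAT	III	286	65	4
PCH2	SYC149	zip1[D10-14] msh4	MAT-RAD18	III	240	103	4
PCH2	SYC149	zip1[D10-14] msh4	RAD18-HMR	III	253	96	3
PCH2	SYC149	zip1[D10-14] msh4	SPO11-SPO13	VIII	247	95	3
PCH2	AF8	zip1[D15-20]	HIS4-CEN3	III	409	139	4
PCH2	AF8	zip1[D15-20]	CEN3-MAT	III	388	172	7
PCH2	AF8	zip1[D15-20]	MAT-RAD18	III	303	232	14
PCH2	AF8	zip1[D15-20]	RAD18-HMR	III	348	199	7
PCH2	AF8	zip1[D15-20]	SPO11-SPO13	VIII	379	168	6
PCH2	AF8	zip1[D15-20]	SPO13-THR1	VIII	433	89	0
PCH2	AF8	zip1[D15-20]	THR1-LYS2	VIII	275	238	9
PCH2	K914	zip1[D15-20] msh4	HIS4-CEN3	III	435	108	0
PCH2	K914	zip1[D15-20] msh4	CEN3-MAT	III	446	104	2
PCH2	K914	zip1[D15-20] msh4	MAT-RAD18	III	334	185	13
PCH2	K914	zip1[D15-20] msh4	RAD18-HMR	III	358	176	4
PCH2	K914	zip1[D15-20] msh4	SPO11-SPO13	VIII	380	134	6
PCH2	AF6	zip1[D21-163]	HIS4-CEN3	III	263	310	10
PCH2	AF6	zip1[D21-163]	CEN3-MAT	III	241	329	13
PCH2	AF6	zip1[D21-163]	MAT-RAD18	III	207	326	17
PCH2	AF6	zip1[D21-163]	RAD18-HMR	III	230	320	11
PCH2	AF6	zip1[D21-163]	SPO11-SPO13	VIII	182	331	44
PCH2	AF6	zip1[D21-163]	SPO13-THR1	VIII	323	194	3
PCH2	AF6	zip1[D21-163]	THR1-LYS2	VIII	161	329	34
PCH2	SYC151	zip1[D21-163] msh4	HIS4-CEN3	III	481	116	2
PCH2	SYC151	zip1[D21-163] msh4	CEN3-MAT	III	496	109	2
PCH2	SYC151	zip1[D21-163] msh4	MAT-RAD18	III	407	185	6
PCH2	SYC151	zip1[D21-163] msh4	RAD18-HMR	III	397	199	4
PCH2	SYC151	zip1[D21-163] msh4	SPO11-SPO13	VIII	437	138	2
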