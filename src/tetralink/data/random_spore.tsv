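strain	genotype	interval	chromosome	r	t
AM3724	pch2	HIS4-CEN3	III	726	2714
AM3724	pch2	CEN3-MAT	III	713	2714
AM3724	pch2	MAT-RAD18	III	975	2714
AM3724	pch2	RAD18-HMR	III	663	2714
AM3724	pch2	SPO11-SPO13	VIII	988	2714
AM3724	pch2	SPO13-THR1	VIII	460	2714
AM3724	pch2	THR1-LYS2	VIII	1066	2714
AM4025	pch2 msh4	HIS4-CEN3	III	142	1684
AM4025	pch2 msh4	CEN3-MAT	III	87	1684
AM4025	pch2 msh4	MAT-RAD18	III	235	1684
AM4025	pch2 msh4	RAD18-HMR	III	180	1684
AM4025	pch2 msh4	SPO11-SPO13	VIII	163	1684
AM4025	pch2 msh4	SPO13-THR1	VIII	119	1684
AM4025	pch2 msh4	THR1-LYS2	VIII	392	1684
AM4023	pch2 zip1	HIS4-CEN3	III	124	1208
AM4023	pch2 zip1	CEN3-MAT	III	134	1208
AM4023	pch2 zip1	MAT-RAD18	III	180	1208
AM4023	pch2 zip1	RAD18-HMR	III	126	1208
AM4023	pch2 zip1	SPO11-SPO13	VIII	267	1208
AM4023	pch2 zip1	SPO13-THR1	VIII	122	1208
AM4023	pch2 zip1	THR1-LYS2	VIII	322	1208
AM3725	pch2 zip1[D2-163]	HIS4-CEN3	III	225	2494
AM3725	pch2 zip1[D2-163]	CEN3-MAT	III	225	2494
AM3725	pch2 zip1[D2-163]	MAT-RAD18	III	409	2494
AM3725	pch2 zip1[D2-163]	RAD18-HMR	III	246	2494
AM3725	pch2 zip1[D2-163]	SPO11-SPO13	VIII	39	2494
AM3725	pch2 zip1[D2-163]	SPO13-THR1	VIII	201	2494
AM3725	pch2 zip1[D2-163]	THR1-LYS2	VIII	606	2494
AM4026	pch2 zip1 msh4	HIS4-CEN3	III	56	529
AM4026	pch2 zip1 msh4	CEN3-MAT	III	63	529
AM4026	pch2 zip1 msh4	MAT-RAD18	III	77	529
AM4026	pch2 zip1 msh4	RAD18-HMR	III	51	529
AM4026	pch2 zip1 msh4	SPO11-SPO13	VIII	154	529
AM4026	pch2 zip1 msh4	SPO13-THR1	VIII	47	529
AM4026	pch2 zip1 msh4	THR1-LYS2	VIII	95	529
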