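strain	interval	cM	se	pct	ratio	ratio_se
AM3724	HIS4-CEN3	31.4	2.1	100	0.47	0.14
AM3724	CEN3-MAT	31.2	2.1	100	0.54	0.16
AM3724	MAT-RAD18	47.8	2.9	100	0.55	0.12
AM3724	RAD18-HMR	27.4	2.0	100	0.57	0.19
AM3724	SPO11-SPO13	51.0	3.2	100	0.84	0.16
AM3724	SPO13-THR1	16.1	1.4	100	0.46	0.27
AM3724	THR1-LYS2	58.5	3.6	100	0.90	0.17
AM4025	HIS4-CEN3	11.7	2.5	37	2.40	1.73
AM4025	CEN3-MAT	6.9	1.8	22	3.09	3.11
AM4025	MAT-RAD18	17.9	2.6	37	0.70	0.50
AM4025	RAD18-HMR	14.2	2.1	52	0.51	0.51
AM4025	SPO11-SPO13	8.9	1.4	17	n.d.	n.d.
AM4025	SPO13-THR1	6.1	1.2	38	n.d.	n.d.
AM4025	THR1-LYS2	28.9	3.4	49	0.56	0.29
AM4023	HIS4-CEN3	8.5	1.9	27	n.d.	n.d.
AM4023	CEN3-MAT	17.0	3.7	54	0.85	0.87
AM4023	MAT-RAD18	21.7	4.9	45	1.46	1.08
AM4023	RAD18-HMR	15.4	4.8	56	4.55	3.33
AM4023	SPO11-SPO13	23.7	3.8	46	0.33	0.34
AM4023	SPO13-THR1	14.4	4.9	89	6.56	1.80
AM4023	THR1-LYS2	23.3	4.0	40	0.39	0.40
AM3725	HIS4-CEN3	7.9	1.0	25	n.d.	n.d.
AM3725	CEN3-MAT	8.9	1.1	26	n.d.	n.d.
AM3725	MAT-RAD18	21.5	2.4	45	0.87	0.40
AM3725	RAD18-HMR	9.7	1.4	35	0.73	0.73
AM3725	SPO11-SPO13	15.2	1.8	30	0.60	0.43
AM3725	SPO13-THR1	5.5	0.9	34	n.d.	n.d.
AM3725	THR1-LYS2	29.8	3.1	51	0.84	0.31
AM4026	HIS4-CEN3	4.3	2.9	14	n.d.	n.d.
AM4026	CEN3-MAT	14.6	4.6	47	n.d.	n.d.
AM4026	MAT-RAD18	31.3	12.4	65	1.71	1.84
AM4026	RAD18-HMR	10.0	4.0	36	n.d.	n.d.
AM4026	SPO11-SPO13	23.8	5.5	47	n.d.	n.d.
AM4026	SPO13-THR1	4.6	3.1	29	n.d.	n.d.
AM4026	THR1-LYS2	34.1	13.4	58	1.50	1.64
K842	HIS4-CEN3	26.7	1.4	100	0.19	0.08
K842	CEN3-MAT	20.1	1.2	100	0.25	0.13
K842	MAT-RAD18	36.3	1.8	100	0.22	0.06
K842	RAD18-HMR	22.9	1.4	100	0.30	0.13
K842	SPO11-SPO13	39.2	2.0	100	0.35	0.08
K842	SPO13-THR1	7.6	0.8	100	0.54	0.54
K842	THR1-LYS2	29.5	1.3	100	0.11	0.05
K852	HIS4-CEN3	10.9	1.1	41	0.35	0.35
K852	CEN3-MAT	5.9	0.9	29	1.41	1.42
K852	MAT-RAD18	24.2	1.9	67	0.55	0.21
K852	RAD18-HMR	12.3	1.0	54	n.d.	n.d.
K852	SPO11-SPO13	11.6	1.4	30	1.22	0.71
K852	SPO13-THR1	3.0	0.6	39	n.d.	n.d.
K852	THR1-LYS2	15.6	1.4	53	0.34	0.25
AM3684	HIS4-CEN3	10.9	1.2	41	1.04	0.61
AM3684	CEN3-MAT	11.7	1.1	58	0.52	0.37
AM3684	MAT-RAD18	27.5	2.3	76	1.10	0.30
AM3684	RAD18-HMR	21.2	1.6	93	0.50	0.21
AM3684	SPO11-SPO13	16.0	1.5	41	0.86	0.39
AM3684	SPO13-THR1	10.4	1.2	137	0.87	0.62
AM3684	THR1-LYS2	28.3	2.2	96	0.69	0.22
K1000	HIS4-CEN3	8.9	1.5	33	2.75	1.61
K1000	CEN3-MAT	13.2	1.5	66	0.94	0.55
K1000	MAT-RAD18	23.3	2.4	64	1.44	0.47
K1000	RAD18-HMR	15.5	1.5	68	0.39	0.28
K1000	SPO11-SPO13	17.2	2.0	44	1.16	0.53
K1000	SPO13-THR1	9.3	1.0	122	n.d.	n.d.
K1000	THR1-LYS2	28.0	2.4	95	0.52	0.21
MP43	HIS4-CEN3	13.9	1.2	52	0.34	0.24
MP43	CEN3-MAT	12.5	1.0	62	0.20	0.20
MP43	MAT-RAD18	24.9	1.7	69	0.44	0.16
MP43	RAD18-HMR	21.0	1.4	92	0.27	0.14
MP43	SPO11-SPO13	14.7	1.2	38	0.30	0.22
MP43	SPO13-THR1	3.4	0.5	45	n.d.	n.d.
MP43	THR1-LYS2	15.6	1.2	53	0.26	0.19
MP46	HIS4-CEN3	13.0	1.5	49	1.21	0.61
MP46	CEN3-MAT	10.6	0.9	53	n.d.	n.d.
MP46	MAT-RAD18	24.2	2.0	67	0.75	0.26
MP46	RAD18-HMR	15.6	1.4	68	0.51	0.30
MP46	SPO11-SPO13	14.0	1.4	36	0.70	0.41
MP46	SPO13-THR1	2.5	0.5	33	n.d.	n.d.
MP46	THR1-LYS2	14.0	1.6	47	1.70	0.54
SYC107	HIS4-CEN3	15.2	1.5	57	0.94	0.43
SYC107	CEN3-MAT	13.1	1.4	65	1.37	0.62
SYC107	MAT-RAD18	22.2	1.5	61	0.33	0.15
SYC107	RAD18-HMR	18.0	1.1	79	n.d.	n.d.
SYC107	SPO11-SPO13	14.6	1.2	37	0.32	0.23
SYC149	HIS4-CEN3	14.6	2.0	55	1.55	0.79
SYC149	CEN3-MAT	12.5	1.9	62	2.35	1.19
SYC149	MAT-RAD18	18.3	2.0	50	0.82	0.42
SYC149	RAD18-HMR	16.2	1.8	71	0.74	0.43
SYC149	SPO11-SPO13	16.4	1.9	42	0.74	0.43
AF8	HIS4-CEN3	14.8	1.4	55	0.75	0.38
AF8	CEN3-MAT	18.9	1.6	94	0.84	0.32
AF8	MAT-RAD18	28.8	2.1	79	0.78	0.22
AF8	RAD18-HMR	21.8	1.7	95	0.58	0.22
AF8	SPO11-SPO13	18.4	1.6	47	0.73	0.31
AF8	SPO13-THR1	8.5	0.8	112	n.d.	n.d.
AF8	THR1-LYS2	28.0	1.9	95	0.43	0.15
K914	HIS4-CEN3	9.9	0.9	37	n.d.	n.d.
K914	CEN3-MAT	10.5	1.1	52	0.71	0.50
K914	MAT-RAD18	24.7	2.2	68	1.20	0.35
K914	RAD18-HMR	18.6	1.5	81	0.42	0.21
K914	SPO11-SPO13	16.4	1.7	42	1.14	0.47
AF6	HIS4-CEN3	31.7	1.8	119	0.28	0.09
AF6	CEN3-MAT	34.9	1.9	174	0.30	0.09
AF6	MAT-RAD18	38.9	2.2	107	0.35	0.09
AF6	RAD18-HMR	34.4	1.9	150	0.25	0.08
AF6	SPO11-SPO13	53.4	3.2	136	0.89	0.16
AF6	SPO13-THR1	20.4	1.4	268	0.24	0.14
AF6	THR1-LYS2	50.9	3.0	173	0.58	0.12
SYC151	HIS4-CEN3	10.7	1.1	40	0.62	0.44
SYC151	CEN3-MAT	10.0	1.0	50	0.73	0.52
SYC151	MAT-RAD18	18.5	1.5	51	0.65	0.27
SYC151	RAD18-HMR	18.6	1.3	81	0.37	0.19
SYC151	SPO11-SPO13	13.0	1.1	33	0.40	0.29
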