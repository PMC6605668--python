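strain	interval	pct	pct_control
AM3724	HIS4-CEN3	26.8	100
AM3724	CEN3-MAT	26.3	100
AM3724	MAT-RAD18	35.9	100
AM3724	RAD18-HMR	24.4	100
AM3724	SPO11-SPO13	36.4	100
AM3724	SPO13-THR1	16.9	100
AM3724	THR1-LYS2	39.3	100
AM4025	HIS4-CEN3	8.4	31
AM4025	CEN3-MAT	5.2	20
AM4025	MAT-RAD18	14.0	39
AM4025	RAD18-HMR	10.7	44
AM4025	SPO11-SPO13	9.7	18
AM4025	SPO13-THR1	7.1	42
AM4025	THR1-LYS2	23.3	59
AM4023	HIS4-CEN3	10.3	38
AM4023	CEN3-MAT	11.1	42
AM4023	MAT-RAD18	14.9	42
AM4023	RAD18-HMR	10.4	43
AM4023	SPO11-SPO13	22.1	61
AM4023	SPO13-THR1	10.1	60
AM4023	THR1-LYS2	26.7	68
AM3725	HIS4-CEN3	9.0	34
AM3725	CEN3-MAT	9.0	34
AM3725	MAT-RAD18	16.4	46
AM3725	RAD18-HMR	9.9	41
AM3725	SPO11-SPO13	13.6	37
AM3725	SPO13-THR1	8.1	48
AM3725	THR1-LYS2	24.3	62
AM4026	HIS4-CEN3	10.6	40
AM4026	CEN3-MAT	11.9	45
AM4026	MAT-RAD18	14.6	41
AM4026	RAD18-HMR	9.6	39
AM4026	SPO11-SPO13	29.1	80
AM4026	SPO13-THR1	8.9	53
AM4026	THR1-LYS2	18.0	46
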