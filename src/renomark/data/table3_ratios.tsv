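timepoint_months	activity_MBq	analyte	percent_of_control	note
4	30	body_weight	110
4	30	wbc	50
4	30	rbc	99
4	30	urea	130
4	30	creatinine	100
4	30	dtpa	66	27.5 min
4	30	dmsa	140
4	60	body_weight	98
4	60	urea	97
4	60	creatinine	100
4	90	body_weight	110
4	90	wbc	53
4	90	rbc	94
4	90	urea	91
4	90	creatinine	100
4	90	dtpa	87	32.5 min
4	90	dmsa	100
4	120	body_weight	99
4	120	urea	92
4	120	creatinine	100
4	150	body_weight	89
4	150	wbc	63
4	150	rbc	95
4	150	urea	91
4	150	creatinine	100
4	150	dtpa	59	32.5 min
4	150	dmsa	120
8	30	body_weight	90
8	30	urea	230
8	30	creatinine	100
8	30	dtpa	62	32.5 min
8	30	dmsa	100
8	60	body_weight	110
8	60	urea	140
8	60	creatinine	100
8	90	body_weight	100
8	90	urea	140
8	90	creatinine	100
8	90	dtpa	270	12.5 min
8	90	dmsa	89
8	120	body_weight	100
8	120	urea	280
8	120	creatinine	100
8	150	body_weight	85
8	150	urea	280
8	150	creatinine	100
8	150	dtpa	450	27.5 min
8	150	dmsa	110
12	30	body_weight	98
12	30	urea	110
12	30	creatinine	100
12	30	dtpa	160	17.5 min
12	30	dmsa	110
12	60	body_weight	120
12	60	urea	82
12	60	creatinine	100
12	90	body_weight	110
12	90	urea	140
12	90	creatinine	100
12	90	dtpa	910	27.5 min
12	120	body_weight	110
12	120	urea	160
12	120	creatinine	100
12	150	body_weight	110
12	150	urea	520
12	150	creatinine	110
12	150	dmsa	100
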