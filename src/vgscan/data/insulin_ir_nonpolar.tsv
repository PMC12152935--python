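region	insulin_residue	ir_domain	ir_residue	pairs1	pairs2	pairs3	traj1	traj2	traj3	reported_average	reported_class
1	Ile A2	aCT'	Phe 714	1	7	7	90.0	50.0	62.9	67.6	m
1	Ile A2	aCT'	His 710	1	2	4	90.0	90.0	55.0	78.3	s
1	Val A3	aCT'	Asp 707	5	7	7	94.0	77.1	78.6	83.2	s
1	Tyr A19	aCT'	Phe 714	3	4	6	86.7	92.5	63.3	80.8	s
1	Tyr A19	aCT'	Val 715	5	2	5	70.0	100.0	70.0	80.0	s
1	Tyr A19	aCT'	Pro 716	15	11	13	45.3	62.7	60.0	56.0	m
2	Gly B8	aCT'	Glu 706	1	1	3	100.0	100.0	83.3	94.4	s
2	Val B12	L1	Leu 37	1	1	1	90.0	100.0	90.0	93.3	s
2	Val B12	L1	Phe 64	2	2	3	55.0	55.0	36.7	48.9	w
2	Val B12	L1	Arg 65	2	3	4	80.0	63.3	60.0	67.8	m
2	Val B12	aCT'	Phe 714	2	2	4	60.0	70.0	37.5	55.8	m
2	Leu B15	aCT'	Phe 714	6	7	6	93.3	84.3	91.7	89.8	s
2	Tyr B16	L1	Phe 39	25	33	19	13.7	25.2	13.1	17.3	w
3	Gly B23	L1	Asn 15	3	3	3	100.0	93.3	96.7	96.7	s
3	Phe B24	L1	Leu 37	5	5	4	86.0	88.0	2.5	58.8	m
3	Phe B24	aCT'	Phe 714	7	8	3	58.6	76.3	66.7	67.2	m
3	Phe B25	aCT'	Pro 716	4	1	4	60.0	100.0	62.5	74.2	s
3	Phe B25	aCT'	Arg 717	11	17	20	84.5	55.3	65.0	68.3	m
3	Phe B25	aCT'	Pro 718	6	2	4	76.7	95.0	80.0	83.9	s
3	Tyr B26	L1	Asp 12	7	7	5	74.3	64.3	88.0	75.5	s
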