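insulin_location	insulin_residue	ir_domain	ir_residue	location	traj1	traj2	traj3	reported_class
A-chain helix 1	Val A3	aCT'	Asn 711	b//s	87.5	87.2	94.3	well_established
A-chain helix 2	Asn A18	aCT'	Arg 717	b//b	99.8	99.5	99.9	well_established
B-chain helix	Ser B9	L1	Arg 65	s//s	96.9	95.5	96.6	well_established
B-chain helix	Glu B13	L1	Arg 65	s//s	79.5	70.3	94.5	well_established
B-chain C-terminus	Phe B24	L1	Asn 15	b//s	99.6	99.7	99.5	well_established
A-chain helix 1	Glu A4	aCT'	Asn 711	s//s	87.2	84.8	36.4	presumable
A-chain helix 2	Asn A21	aCT'	Arg 717	b//b	97.9	35.6	94.6	presumable
B-chain N-terminus	Asn B3	FnIII-1'	Lys 544	s//s	42.2	40.3	0.0	presumable
B-chain N-terminus	Asn B3	FnIII-1'	Lys 544	s//b	78.6	38.9	15.8	presumable
B-chain helix	His B10	FnIII-1'	Ser 540	s//b	91.3	76.5	0.0	presumable
B-chain C-terminus	Glu B21	L1	Lys 40	s//s	71.0	32.2	26.7	presumable
B-chain C-terminus	Thr B30	CR	Gln 272	b//b	84.2	96.6	11.1	presumable
B-chain C-terminus	Thr B30	CR	Gly 273	b//b	90.0	96.4	10.1	presumable
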