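# Specific inter-protein interactions (hydrogen bonds and salt bridges) of
# the three leading docked HSA-ACE complexes over a 100 ns MD simulation,
# with their lifetime as a percentage of the simulation length. Superscript
# backbone participation is given in the backbone_a / backbone_b columns
# (O = backbone carbonyl oxygen, HN = backbone amide).
# columns: complex_id, residue_hsa, backbone_hsa, residue_ace, backbone_ace, kind, lifetime_percent
4	Asp1	HN	Glu320		SB	29
4	Asp13		Ser281		HB	75
4	Glu17		Tyr265		HB	65
4	Glu17		Asn423		HB	18
4	Lys20		Asp266		SB	86
4	Glu37		Arg236		SB	66
4	Glu37		Lys622		SB	19
4	Asp38		Lys622		SB	91
4	Lys41		Asp616		SB	17
4	Ala55	O	Arg350		HB	67
4	Glu57		Arg350		SB	76
4	Thr79		Glu619		HB	5
4	Asn111	O	Arg629		HB	5
4	His128	O	Asn588		HB	30
4	Asp129		Arg235		SB	96
4	Lys159		Asp273		SB	63
4	Lys162		Asp273		SB	89
4	Glu280		Arg413		SB	67
4	Lys286		Asp412		SB	11
4	Glu505		Lys914		SB	71
4	Glu505	O	Lys939		HB	43
4	Asp512		Lys971		SB	86
4	Glu565		Lys1132		SB	34
7	Gln33	O	Ser804		HB	80
7	Cys34	O	Gln807		HB	27
7	Phe36	HN	Glu806		SB	22
7	Glu37		Arg1046		SB	83
7	Asp38		Arg797		SB	98
7	Lys41		Asp1049		SB	99
7	Thr79		Asp794		HB	6
7	Arg81		Asp605		SB	85
7	Glu82		Lys689		SB	61
7	Thr83		Ser798		HB	23
7	Glu86		Arg240		SB	98
7	Asp89		Arg240		SB	80
7	Glu97		Thr478	HN	HB	36
7	Arg114		Glu815		SB	39
7	Arg117	O	Gln814		HB	46
7	Asp129		Lys1067		SB	48
7	Lys137		Glu810		SB	68
7	Lys205		Glu596		SB	11
7	Asp512		Arg1137		SB	7
7	Glu565		Lys1132		SB	6
6	Lys159		Glu327		SB	74
6	Lys162		Ile46	O	HB	58
6	Glu167		Lys126		SB	94
6	Glu184		Lys132		SB	37
6	Glu277		Thr144		HB	7
6	Glu277		Arg350		SB	44
6	Glu280		Arg350		SB	74
6	Glu297		Arg236		SB	8
6	Tyr334		Glu626		HB	14
6	Tyr334		Arg629		HB	5
6	Tyr341		Glu626		HB	16
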