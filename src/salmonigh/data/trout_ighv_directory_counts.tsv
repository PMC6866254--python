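# Rainbow trout IGHV alleles in the V reference directory (F + ORF + in-frame P),
# per subgroup, locus and functionality; all alleles are *01 (genes == alleles).
# Directory census: 77 alleles = 44 F + 11 ORF + 22 in-frame P.
subgroup	locus_id	functionality	genes	alleles
1	A	F	6	6
1	A	P	2	2
1	B	F	5	5
1	B	ORF	2	2
1	B	P	2	2
2	A	F	2	2
2	A	P	1	1
2	B	F	3	3
2	B	P	2	2
3	A	F	1	1
3	B	ORF	1	1
4	A	P	1	1
4	B	F	4	4
4	B	P	4	4
6	A	F	2	2
6	A	ORF	1	1
6	B	F	3	3
6	B	P	2	2
7	B	ORF	4	4
8	A	F	4	4
8	A	ORF	1	1
8	A	P	1	1
9	A	F	3	3
9	A	P	1	1
9	B	F	1	1
10	A	F	1	1
10	B	F	3	3
11	A	F	1	1
12	B	F	4	4
14	A	P	1	1
15	B	F	1	1
15	B	P	2	2
16	A	ORF	2	2
16	A	P	2	2
16	B	P	1	1
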