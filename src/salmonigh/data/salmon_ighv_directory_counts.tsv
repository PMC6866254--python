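# Atlantic salmon IGHV alleles in the V reference directory (F + ORF + in-frame P),
# per subgroup, locus and functionality. genes = number of genes represented;
# alleles = number of alleles (> genes when a gene contributes *02/*03 alleles).
# Directory release census: 150 alleles = 76 F + 15 ORF + 59 in-frame P over 135 genes.
subgroup	locus_id	functionality	genes	alleles
1	A	F	7	7
1	A	ORF	1	2
1	A	P	5	6
1	B	F	12	14
1	B	ORF	2	2
1	B	P	6	7
2	A	F	2	2
2	B	F	3	3
3	A	F	1	2
3	B	F	1	1
3	B	P	1	1
4	A	F	2	2
4	A	ORF	2	2
4	A	P	4	4
4	B	F	3	3
4	B	ORF	1	1
4	B	P	2	2
5	A	ORF	2	3
6	A	F	1	2
6	A	ORF	1	1
6	A	P	3	3
6	B	F	6	6
6	B	P	3	4
7	A	F	1	1
7	A	P	1	1
7	B	P	1	1
8	A	F	11	14
8	A	ORF	1	2
8	A	P	1	1
8	B	F	3	3
9	A	F	1	1
9	A	P	1	1
9	B	F	3	3
9	B	P	3	3
10	A	P	5	5
10	B	ORF	1	1
10	B	P	3	3
11	A	F	2	2
11	A	P	1	2
12	B	F	1	1
12	B	ORF	1	1
14	A	P	1	1
15	A	F	1	1
15	A	P	1	1
15	B	F	2	2
15	B	P	2	3
16	A	F	1	1
16	A	P	3	3
16	B	F	5	5
16	B	P	7	7
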