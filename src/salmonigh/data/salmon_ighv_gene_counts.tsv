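# Atlantic salmon IGHV gene counts per subgroup and locus (gene-level census).
# functional/orf/pseudogene are counts of genes whose single functionality is that class;
# mixed_f_p counts genes carrying both an F and a P allele (printed as "(+1)" in both the
# Functional and Pseudogene columns of the source census; known cases: IGHV8-58 locus A
# subgroup 8, IGHV2D-12 locus B subgroup 2).
subgroup	locus_id	functional	orf	pseudogene	mixed_f_p	total
1	A	7	1	24	0	32
2	A	2	0	0	0	2
3	A	1	0	4	0	5
4	A	2	2	12	0	16
5	A	0	2	2	0	4
6	A	1	1	16	0	18
7	A	1	0	2	0	3
8	A	10	1	9	1	21
9	A	1	0	4	0	5
10	A	0	0	14	0	14
11	A	2	0	6	0	8
12	A	0	0	1	0	1
13	A	0	0	1	0	1
14	A	0	0	1	0	1
15	A	1	0	5	0	6
16	A	1	0	7	0	8
1	B	12	2	23	0	37
2	B	2	0	5	1	8
3	B	1	0	5	0	6
4	B	3	1	14	0	18
5	B	0	0	4	0	4
6	B	6	0	20	0	26
7	B	0	0	3	0	3
8	B	3	0	5	0	8
9	B	3	0	5	0	8
10	B	0	1	8	0	9
11	B	0	0	6	0	6
12	B	1	1	0	0	2
13	B	0	0	2	0	2
14	B	0	0	1	0	1
15	B	2	0	3	0	5
16	B	5	0	10	0	15
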