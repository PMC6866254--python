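# Atlantic salmon IGH constant genes and associated D and J genes, plus the dispersed
# D genes located among the V genes. Names are transcribed verbatim from the printed
# gene table (including the I/1 typographic confusions IGHJIT4, IGHJIT5, IGHJID, which
# the loader normalizes); `cluster` is the printed D-J-C cluster membership (tau series
# tag, M for the IGHM/IGHD cluster, DISPERSED for D genes among the V genes).
# Multi-valued functionality ("F, ORF") means alleles of differing functionality.
species	locus_id	group	name	cluster	functionality
Salsal	A	C	IGHT1	T1	P
Salsal	A	D	IGHD1T2	T2	F
Salsal	A	D	IGHD2T2	T2	F
Salsal	A	J	IGHJ1T2	T2	F
Salsal	A	J	IGHJ2T2	T2	F
Salsal	A	C	IGHT2	T2	P
Salsal	A	J	IGHJ1T3	T3	F
Salsal	A	J	IGHJ2T3	T3	F
Salsal	A	C	IGHT3	T3	P
Salsal	A	D	IGHD1T4	T4	F
Salsal	A	D	IGHD2T4	T4	F
Salsal	A	D	IGHD3T4	T4	F
Salsal	A	D	IGHD4T4	T4	F
Salsal	A	D	IGHD5T4	T4	F
Salsal	A	J	IGHJIT4	T4	F
Salsal	A	J	IGHJ2T4	T4	F
Salsal	A	C	IGHT4	T4	F
Salsal	A	D	IGHD1T5	T5	F
Salsal	A	J	IGHJIT5	T5	P
Salsal	A	J	IGHJ2T5	T5	F
Salsal	A	C	IGHT5	T5	P
Salsal	A	D	IGHD1	M	F
Salsal	A	D	IGHD2	M	F
Salsal	A	D	IGHD3	M	F
Salsal	A	D	IGHD4	M	F
Salsal	A	D	IGHD5	M	F
Salsal	A	D	IGHD6	M	F
Salsal	A	D	IGHD7	M	F
Salsal	A	D	IGHD8	M	F
Salsal	A	D	IGHD9	M	F
Salsal	A	J	IGHJ1	M	F
Salsal	A	J	IGHJ2	M	ORF
Salsal	A	J	IGHJ3	M	F
Salsal	A	J	IGHJ4	M	F
Salsal	A	J	IGHJ5	M	F, ORF
Salsal	A	C	IGHM	M	F
Salsal	A	C	IGHD	M	F
Salsal	A	D	IGHD-1	DISPERSED	F
Salsal	A	D	IGHD-2	DISPERSED	F
Salsal	A	D	IGHD-3	DISPERSED	F
Salsal	A	D	IGHD-4	DISPERSED	F
Salsal	A	D	IGHD-5	DISPERSED	F
Salsal	A	D	IGHD-6	DISPERSED	F
Salsal	A	D	IGHD-7	DISPERSED	F
Salsal	A	D	IGHD-8	DISPERSED	F
Salsal	A	D	IGHD-9	DISPERSED	F
Salsal	A	D	IGHD-10	DISPERSED	F
Salsal	A	D	IGHD-11	DISPERSED	F
Salsal	B	J	IGHJ1T1D	T1	P
Salsal	B	C	IGHT1D	T1	P
Salsal	B	D	IGHD1T2D	T2	F
Salsal	B	D	IGHD2T2D	T2	F
Salsal	B	J	IGHJ1T2D	T2	F
Salsal	B	J	IGHJ2T2D	T2	F
Salsal	B	C	IGHT2D	T2	F
Salsal	B	D	IGHD1T3D	T3	F
Salsal	B	D	IGHD2T3D	T3	F
Salsal	B	D	IGHD3T3D	T3	F
Salsal	B	C	IGHT3D	T3	P
Salsal	B	D	IGHD1D	M	F
Salsal	B	D	IGHD2D	M	F
Salsal	B	D	IGHD3D	M	F
Salsal	B	D	IGHD4D	M	F
Salsal	B	D	IGHD5D	M	F
Salsal	B	D	IGHD6D	M	F
Salsal	B	J	IGHJID	M	F
Salsal	B	J	IGHJ2D	M	F
Salsal	B	J	IGHJ3D	M	F
Salsal	B	J	IGHJ4D	M	F
Salsal	B	J	IGHJ5D	M	F, ORF
Salsal	B	C	IGHMD	M	F
Salsal	B	C	IGHDD	M	F
Salsal	B	D	IGHD-1D	DISPERSED	F
Salsal	B	D	IGHD-2D	DISPERSED	F
Salsal	B	D	IGHD-3D	DISPERSED	F
Salsal	B	D	IGHD-4D	DISPERSED	F
Salsal	B	D	IGHD-5D	DISPERSED	F
Salsal	B	D	IGHD-6D	DISPERSED	F
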