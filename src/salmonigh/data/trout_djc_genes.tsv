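# Rainbow trout IGH constant genes and associated D and J genes. The IGHMD
# functionality cell is blank in the source gene table (its functionality is
# argued in the text but not stated in the table); the loader records it as
# "unstated" rather than guessing.
species	locus_id	group	name	cluster	functionality
Oncmyk	A	D	IGHD1T1	T1	F
Oncmyk	A	D	IGHD2T1	T1	F
Oncmyk	A	D	IGHD3T1	T1	F
Oncmyk	A	J	IGHJ1T1	T1	F
Oncmyk	A	J	IGHJ2T1	T1	F
Oncmyk	A	C	IGHT1	T1	P
Oncmyk	A	D	IGHD1T2	T2	F
Oncmyk	A	D	IGHD2T2	T2	F
Oncmyk	A	J	IGHJ1T2	T2	F
Oncmyk	A	J	IGHJ2T2	T2	F
Oncmyk	A	C	IGHT2	T2	F
Oncmyk	A	D	IGHD1	M	F
Oncmyk	A	D	IGHD2	M	F
Oncmyk	A	D	IGHD3	M	F
Oncmyk	A	D	IGHD4	M	F
Oncmyk	A	D	IGHD5	M	F
Oncmyk	A	D	IGHD6	M	F
Oncmyk	A	J	IGHJ1	M	F
Oncmyk	A	J	IGHJ2	M	F
Oncmyk	A	J	IGHJ3	M	F
Oncmyk	A	J	IGHJ4	M	F
Oncmyk	A	J	IGHJ5	M	F
Oncmyk	A	J	IGHJ6	M	F
Oncmyk	A	C	IGHM	M	F
Oncmyk	A	C	IGHD	M	F
Oncmyk	B	D	IGHD1T1D	T1	F
Oncmyk	B	D	IGHD2T1D	T1	F
Oncmyk	B	D	IGHD3T1D	T1	ORF
Oncmyk	B	D	IGHD4T1D	T1	F
Oncmyk	B	J	IGHJ1T1D	T1	F
Oncmyk	B	J	IGHJ2T1D	T1	F
Oncmyk	B	C	IGHT1D	T1	F
Oncmyk	B	D	IGHD1D	M	F
Oncmyk	B	D	IGHD2D	M	F
Oncmyk	B	D	IGHD3D	M	F
Oncmyk	B	D	IGHD4D	M	F
Oncmyk	B	D	IGHD5D	M	F
Oncmyk	B	D	IGHD6D	M	F
Oncmyk	B	J	IGHJ1D	M	F
Oncmyk	B	J	IGHJ2D	M	F
Oncmyk	B	J	IGHJ3D	M	F
Oncmyk	B	J	IGHJ4D	M	F
Oncmyk	B	J	IGHJ5D	M	F
Oncmyk	B	J	IGHJ6D	M	F
Oncmyk	B	J	IGHJ7D	M	F
Oncmyk	B	C	IGHMD	M
Oncmyk	B	C	IGHDD	M	F
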