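patient_id	zygosity	allele1	allele2	allele1_class	allele2_class	sex	age_years	deceased	seizures	cognitive	brain_malformation	muscle_movement	cos_printed
1	compound_heterozygous	P509A	E597K	missense	missense			False	1		3	2	6
3	compound_heterozygous	D295Y	R536Q	missense	missense			False	3			3	6
9	compound_heterozygous	A202V	IVS22+1G>C	missense	intronic_splice			False	1	1			2
10	compound_heterozygous	A202V	IVS22+1G>C	missense	intronic_splice			False	1	1			2
11	compound_heterozygous	A802V	IVS22+1G>A	missense	intronic_splice			False	1	1			2
12	compound_heterozygous	A802V	IVS22+1G>A	missense	intronic_splice			False	1	1			2
13	compound_heterozygous	A389V	IVS12+2T>G	missense	intronic_splice			False	1	1			2
14	compound_heterozygous	A389V	IVS12+2T>G	missense	intronic_splice			False	1	1			2
26	compound_heterozygous	P267A	K376E	missense	missense			False	1	2			3
27	compound_heterozygous	R373W	intronic	missense	intronic_splice			False	1	1			2
28	compound_heterozygous	R373W	M1I	missense	mito_leader			False	1	1			2
31	compound_heterozygous	H371D	del GLDC	missense	deletion			False	1		3	3	7
51	compound_heterozygous	N150T	R790W	missense	missense			False	1	3	0	2	6
52	compound_heterozygous	L82W	607fs	missense	nonsense_frameshift			False	1	1	0	2	4
54	compound_heterozygous	C1002W	S419X	missense	nonsense_frameshift			False	3	2			5
55	compound_heterozygous	C1002W	S419X	missense	nonsense_frameshift			False		2		2	4
56	compound_heterozygous	Q620R	del Exon 3-9	missense	deletion			False	3		0	3	6
57	compound_heterozygous	S132L	S86Vfs_119	missense	nonsense_frameshift			False	3		3	2	8
68	compound_heterozygous	T894A	del Exon3	missense	deletion			False	3	3		2	8
69	compound_heterozygous	Y839C	intronic	missense	intronic_splice			False	3		3	3	9
73	compound_heterozygous	G771R	M552V	missense	missense			False	1			2	3
74	compound_heterozygous	R739H	del Exon 1-2	missense	deletion			False	1	1	0	1	3
76	compound_heterozygous	R461Q	del GLDC	missense	deletion			False	1	2	3	2	8
85	compound_heterozygous	G761R	Y632X	missense	nonsense_frameshift			False	3	3	3		9
86	compound_heterozygous	R515S	IVS19-1G>A	missense	intronic_splice			False	1	3	3		7
87	compound_heterozygous	S132L	E167X	missense	nonsense_frameshift			False	3	3	3		9
89	compound_heterozygous	P907L	del Exon 1-24	missense	deletion			False		3	3		6
90	compound_heterozygous	R515S	G618R	missense	missense			False		3	3		6
91	compound_heterozygous	A733V	IVS19-1G>A	missense	intronic_splice			False	1	3			4
95	compound_heterozygous	R515S	IVS19-1G>A	missense	intronic_splice			False		3	3		6
97	compound_heterozygous	L885P	Y637X	missense	nonsense_frameshift			False		3	3		6
98	compound_heterozygous	G771R	IVS19-1G>A	missense	intronic_splice			False		3	3		6
100	compound_heterozygous	F334L	del GLDC	missense	deletion			False		3	3		6
101	compound_heterozygous	A389V	R515S	missense	missense			False		3	3		6
102	compound_heterozygous	L548V	del GLDC	missense	deletion			False	1	2			3
103	compound_heterozygous	A802V	IVS22+1G>C	missense	intronic_splice			False	1	2			3
104	compound_heterozygous	A802V	R515S	missense	missense			False	1	2			3
105	compound_heterozygous	A389V	R515S	missense	missense			False	3	1			4
106	compound_heterozygous	I381T	R461Q	missense	missense			False	1	1			2
107	compound_heterozygous	A283P	R461Q	missense	missense			False	3	1			4
108	compound_heterozygous	A283P	R461Q	missense	missense			False	1	1			2
109	compound_heterozygous	R461Q	IVS12+2T>G	missense	intronic_splice			False	1	1			2
110	compound_heterozygous	Y161C	R347S	missense	missense			False	1	1			2
111	compound_heterozygous	G156R	G728E	missense	missense			False	1	1			2
112	compound_heterozygous	R630P	L548V	missense	missense			False	1	1			2
113	compound_heterozygous	A802E	IVS19+2T>G	missense	intronic_splice			False	1	1			2
114	compound_heterozygous	V905G	G728E	missense	missense			False	1	1			2
115	compound_heterozygous	G652E	R373Q	missense	missense			False	1	1			2
129	compound_heterozygous	L885P	W897C	missense	missense			False	3	3	3	3	12
131	compound_heterozygous	A377V	A694Dfs	missense	nonsense_frameshift			False	3	3	0	2	8
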