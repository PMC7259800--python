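patient_id	allele1	allele2	cos	predicted_severity	allele1_region	allele2_region	mms
1	P509A	E597K	6	S	none	none	2.0
3	D295Y	R536Q	6	S	none	dimerization	4.5
26	P267A	K376E	3	A	N PLP	H-interface	3.0
51	N150T	R790W	6	S	dimerization	none	4.5
73	G771R	M552V	3	A	none	dimerization	4.5
90	R515S	G618R	6	S	none	active site	6.0
101	A389V	R515S	6	S	none	none	3.5
104	A802V	R515S	3	A	N PLP	none	3.5
105	A389V	R515S	4	A	none	none	3.5
106	I381T	R461Q	2	A	none	none	3.5
107	A283P	R461Q	4	A	none	none	2.0
108	A283P	R461Q	2	A	none	none	2.0
110	Y161C	R347S	2	A	active site	none	3.5
111	G156R	G728E	2	A	none	none	6.0
112	R630P	L548V	2	A	none	dimerization	4.5
114	V905G	G728E	2	A	none	none	5.5
115	G652E	R373Q	2	A	none	H-interface	3.5
129	L885P	W897C	12	S	none	active site	5.5
9	A202V	IVS22+1G>C	2	A	none	N/A	2.5
10	A202V	IVS22+1G>C	2	A	none	N/A	2.5
11	A802V	IVS22+1G>A	2	A	N PLP	N/A	2.5
12	A802V	IVS22+1G>A	2	A	N PLP	N/A	2.5
13	A389V	IVS12+2T>G	2	A	none	N/A	2.5
14	A389V	IVS12+2T>G	2	A	none	N/A	2.5
27	R373W	splice site	2	A	H-interface	N/A	3
69	Y839C	splice site	9	S	none	N/A	3
86	R515S	IVS19-1G>A	7	S	none	N/A	3
91	A733V	IVS19-1G>A	4	A	none	N/A	3.5
95	R515S	IVS19-1G>A	6	S	none	N/A	3
98	G771R	IVS19-1G>A	6	S	none	N/A	3.5
103	A802V	IVS22+1G>C	3	A	N PLP	N/A	2.5
109	R461Q	IVS12+2T>G	2	A	none	N/A	2.5
113	A802E	IVS19+2T>G	2	A	N PLP	N/A	2.5
31	H371D	del GLDC	7	S	none	N/A	2
56	Q620R	del Exon 3-9	6	S	none	N/A	2.5
68	T894A	del Exon 3	8	S	active site	N/A	2.5
74	R739H	del Exon 1-2	3	A	none	N/A	2.5
76	R461Q	del GLDC	8	S	none	N/A	3
89	P907L	del Exon 1-24	6	S	none	N/A	2.5
100	F334L	del GLDC	6	S	none	N/A	3.5
102	L548V	del GLDC	3	A	dimerization	N/A	3
52	L82W	607fs	4	A	none	N/A	2.5
54	C1002W	S419X	5	A	none	N/A	3.5
55	C1002W	S419X	4	A	none	N/A	2.5
57	S132L	S86Vfs_119	8	S	none	N/A	2.5
85	G761R	Y632X	9	S	none	N/A	3.5
87	S132L	E167X	9	S	none	N/A	2.5
97	L885P	Y637X	6	S	none	N/A	3
131	A377V	A694Dfs	8	S	none	N/A	2
28	R373W	M1I	2	A	H-interface	mito leader seq	3
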