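patient_id	allele1	allele2	cos	predicted_severity	allele1_region	allele2_region	mms
5	I372F	I372F	9	S	H-interface	H-interface	4.0
17	R362C	R362C	2	A	none	none	5.0
32	T187K	T187K	3	A	none	none	5.0
43	A389V	A389V	3	A	none	none	2.0
44	A389V	A389V	5	A	none	none	2.0
45	A802V	A802V	2	A	N-term PLP	N-term PLP	2.0
46	A802V	A802V	0	A	N-term PLP	N-term PLP	2.0
47	A802V	A802V	0	A	N-term PLP	N-term PLP	2.0
48	A802V	A802V	3	A	N-term PLP	N-term PLP	2.0
49	R739H	R739H	4	A	none	none	3.0
52	Y623H	Y623H	3	A	none	none	3.0
57	Y164H	Y164H	5	A	Active Site	Active Site	2.0
58	Y164H	Y164H	4	A	Active Site	Active Site	2.0
59	Y164H	Y164H	2	A	Active Site	Active Site	2.0
60	Y161C	Y161C	12	S	Active Site	Active Site	4.0
62	R988Q	R988Q	7	S	none	none	2.0
71	P949L	P949L	9	S	none	none	5.0
74	P581R	P581R	7	S	none	none	7.0
76	A202V	A202V	2	A	none	none	2.0
77	H950R	H950R	9	S	none	none	4.0
78	Q366R	Q366R	3	A	H-interface	H-interface	2.0
80	R515S	R515S	9	S	none	none	5.0
82	T269M	T269M	2	A	none	none	1.0
129	D198V	D198V	9	S	N-term PLP	N-term PLP	5.0
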