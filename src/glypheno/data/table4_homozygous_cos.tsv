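patient_id	zygosity	allele1	allele2	allele1_class	allele2_class	sex	age_years	deceased	seizures	cognitive	brain_malformation	muscle_movement	cos_printed
5	homozygous	I372F	I372F	missense	missense			False	3		3	3	9
8	homozygous	C291Y	C291Y	missense	missense			False	1	1			2
17	homozygous	R362C	R362C	missense	missense			False	1	1			2
44	homozygous	A389V	A389V	missense	missense			False		1		2	3
45	homozygous	A389V	A389V	missense	missense			False	1	2		2	5
46	homozygous	A802V	A802V	missense	missense			False	0	0		2	2
47	homozygous	A802V	A802V	missense	missense			False	0	0		0	0
48	homozygous	A802V	A802V	missense	missense			False	0	0		0	0
49	homozygous	A802V	A802V	missense	missense			False	0	1		2	3
50	homozygous	R739H	R739H	missense	missense			False	1	1		2	4
53	homozygous	Y623H	Y623H	missense	missense			False	1	1		1	3
58	homozygous	Y164H	Y164H	missense	missense			False	1	2	0	2	5
59	homozygous	Y164H	Y164H	missense	missense			False	1	2		1	4
60	homozygous	Y164H	Y164H	missense	missense			False	1	1		0	2
62	homozygous	Y161C	Y161C	missense	missense			False	3	3	3	3	12
63	homozygous	R988Q	R988Q	missense	missense			False	1		3	3	7
72	homozygous	P949L	P949L	missense	missense			False	3	3	3		9
75	homozygous	P581R	P581R	missense	missense			False	1	3	3		7
77	homozygous	A202V	A202V	missense	missense			False	1	1			2
78	homozygous	H950R	H950R	missense	missense			False	3	3	3		9
79	homozygous	Q366R	Q366R	missense	missense			False	1	2			3
81	homozygous	R515S	R515S	missense	missense			False	3	3	3		9
83	homozygous	T269M	T269M	missense	missense			False	1	1			2
130	homozygous	D198V	D198V	missense	missense			False	3		3	3	9
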