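allele1	allele2	cos	mms
E503A	V233A	0	2.0
E503A	T799S	0	2.0
E503A	R236Q	0	2.0
E503A	V705M	0	1.5
T799S	V747I	0	3.0
V800I	A414T	0	2.0
E503A	N533S	0	2.5
P509A	I301M	0	1.0
P509A	G137S	0	2.0
E503A	R596Q	0	2.0
E503A	S814F	0	5.0
V705M	A64S	0	1.5
A794T	L462V	0	0.5
L207V	N193S	0	0.5
E669K	N413Y	0	2.5
V735L	V233A	0	2.0
V735L	R66K	0	2.0
E278K	A64T	0	1.5
V735L	A569T	0	2.5
A569T	Mito Leader Sequence	0	3.0
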