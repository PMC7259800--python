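mutation	n_exac_homozygotes	cos	mms
M107V	80	0.0	0.0
R224H	22	0.0	2.0
C291G	6	0.0	2.0
R410K	8	0.0	0.0
L462V	122	0.0	0.0
E503A	14	0.0	2.0
A569T	4	0.0	2.0
V705M	1	0.0	1.0
V735L	8	0.0	2.0
A794T	3	0.0	1.0
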