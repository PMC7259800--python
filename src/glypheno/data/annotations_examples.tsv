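mutation	position	ref_aa	alt_aa	ddg_kcal_mol	conservation_grade	blosum62	sec_struct	active_site	active_region_7A	nterm_plp	h_interface	dimer_interface
R515S	515	R	S	-2.47	9	-1	loop	0	0	0	0	0
A389V	389	A	V	0.0	9	0	helix	0	0	0	0	0
A802V	802	A	V	0.0	3	0	loop	0	0	1	0	0
T269M	269	T	M	0.0	3	-1	loop	0	0	0	0	0
S564I	564	S	I	-3.23	8	-2	sheet	0	0	0	0	0
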