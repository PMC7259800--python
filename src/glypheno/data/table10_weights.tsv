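parameter	label	unweighted	homozygous_trained	heterozygous_trained
stabilizing	Stability (Stabilizing)	1.0	-1.20	0.69
destabilizing	Stability (Destabilizing)	1.0	-0.95	0.94
cons_residue	Conservation of Residue	1.0	3.43	1.30
cons_substitution	Conservation of Substitution	-1.0	-3.97	-2.35
helix	Helix	1.0	2.96	2.78
sheet	Sheet	1.0	-0.26	4.18
c_term	C-term	1.0	2.56	1.50
active_site	Active Site	1.0	2.48	3.92
active_region	Active Region	1.0	0.00	-5.74
nterm_plp	N-term PLP	1.0	3.00	0.94
h_interface	H-interface	1.0	2.55	-0.43
dimer_interface	Dimerization Interface	1.0	-2.48	-0.62
d_polarity	D Polarity	1.0	-0.82	-2.06
d_charge	D Charge	1.0	0.57	1.61
d_aromaticity	D Aromaticity	1.0	4.62	-0.32
d_proline	D Proline	1.0	2.59	2.14
d_codon	D Codon availability	1.0	0.23	0.40
d_size	D Size	1.0	-1.26	1.34
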