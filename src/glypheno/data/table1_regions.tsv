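region	total_residues	n_mutated	rate_printed	p_printed
whole_protein	1020	213	0.209
full_active_site	30	10	0.333	0.08
nterm_plp	20	6	0.300	0.22
h_interface	17	6	0.353	0.12
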