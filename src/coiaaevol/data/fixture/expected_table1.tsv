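order	n_bins	n_families	order_distance	family_distance	bin_distance	overall_distance	se_order	se_family	se_bin
Alphida	10	4	0.328	0.194	0.071	0.198	0.008	0.005	0.016
Betida	8	3	0.45	0.279	0.1	0.276	0.005	0.002	0.026
Deltida	6	2	0.419	0.254	0.097	0.257	0.035	0.0	0.014
Gammida	9	3	0.565	0.47	0.152	0.395	0.028	0.006	0.047
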