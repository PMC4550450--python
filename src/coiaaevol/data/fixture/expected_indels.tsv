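kind	start_site	length	support	families	region	origins
deletion	119	1	1	Gammida_F01	unknown	1
deletion	128	4	3	Gammida_F03	unknown	1
deletion	159	5	3	Gammida_F03	unknown	1
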