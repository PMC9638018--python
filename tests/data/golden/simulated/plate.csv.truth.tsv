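# immetab 0.1.0 config_sha256=aed6c506bf408ec1
well	true_concentration	a	b	c	d
U1	50	0.05	1.2	250	3.2
U2	120	0.05	1.2	250	3.2
U3	300	0.05	1.2	250	3.2
U4	700	0.05	1.2	250	3.2
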