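# immetab 0.1.0 config_sha256=aed6c506bf408ec1
metabolite	mass_shift	true_mid	ion_count_scale	noise_cv
succinate	0	0.15	1000000	0.01
succinate	1	0.03	1000000	0.01
succinate	2	0.04	1000000	0.01
succinate	3	0.08	1000000	0.01
succinate	4	0.7	1000000	0.01
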