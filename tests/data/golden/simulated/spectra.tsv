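# immetab 0.1.0 config_sha256=aed6c506bf408ec1
sample	metabolite	mass_shift	ion_count	internal_standard_count
s000	succinate	0	110753.5081	500000
s000	succinate	1	49151.99386	500000
s000	succinate	2	46820.00235	500000
s000	succinate	3	71015.25513	500000
s000	succinate	4	553667.3094	500000
s001	succinate	0	110133.3005	500000
s001	succinate	1	48765.22216	500000
s001	succinate	2	46224.1772	500000
s001	succinate	3	71913.66682	500000
s001	succinate	4	545155.3589	500000
s002	succinate	0	112463.6728	500000
s002	succinate	1	48441.45617	500000
s002	succinate	2	46565.83986	500000
s002	succinate	3	71281.15801	500000
s002	succinate	4	553218.3177	500000
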