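# immetab 0.1.0 config_sha256=aed6c506bf408ec1
sample	metabolite	M0	M1	M2	M3	M4	fractional_enrichment	relative_abundance	labeled_abundance
s000	succinate	0.1502415452	0.03091689611	0.04060673539	0.07942190292	0.6988129203	0.7864119393	1.662816138	1.412992072
s001	succinate	0.1511704195	0.03095659711	0.04044328605	0.08173771267	0.6956919847	0.7849560615	1.644383451	1.395801315
s002	succinate	0.1524927954	0.02940893998	0.04035722022	0.07989103774	0.6978500067	0.7852991301	1.663940889	1.410201892
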