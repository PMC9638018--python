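# immetab 0.1.0 config_sha256=aed6c506bf408ec1
well	cytokine	raw_concentration	corrected_concentration	per_1e6_cells
U1	IFN-gamma	51.04160718	51.04160718	255.2080359
U2	IFN-gamma	124.6001058	124.6001058	623.000529
U3	IFN-gamma	299.8796742	299.8796742	1499.398371
U4	IFN-gamma	687.6908333	687.6908333	3438.454167
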