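# immetab 0.1.0 config_sha256=aed6c506bf408ec1
well,role,known_concentration,od,input_cell_count,viability_fraction
STD1,standard,2000,2.969249314,,
STD2,standard,1000,2.703806009,,
STD3,standard,500,2.242405797,,
STD4,standard,250,1.615119214,,
STD5,standard,125,0.9870888772,,
STD6,standard,62.5,0.5569888253,,
STD7,standard,31.25,0.2935655772,,
STD8,standard,15.625,0.1510767008,,
U1,unknown,,0.4540733149,200000,1
U2,unknown,,0.994538392,200000,1
U3,unknown,,1.786947142,200000,1
U4,unknown,,2.477543727,200000,1
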