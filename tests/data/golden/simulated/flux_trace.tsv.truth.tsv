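# immetab 0.1.0 config_sha256=aed6c506bf408ec1
well	phase	true_ocr	true_ecar	noise_sd
W1	basal	100	15	1.5
W1	glucose	105	60	1.5
W1	oligomycin	40	80	1.5
W1	bam15	160	70	1.5
W1	rotenone_antimycin	15	40	1.5
W2	basal	100	15	1.5
W2	glucose	105	60	1.5
W2	oligomycin	40	80	1.5
W2	bam15	160	70	1.5
W2	rotenone_antimycin	15	40	1.5
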