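# immetab 0.1.0 config_sha256=aed6c506bf408ec1
well	atp_coupled_ocr	basal_glycolysis	ocr_ecar_ratio	mito_atp	glyco_atp	total_atp
W1	67.11530816	46.65392497	1.438577959	369.1341949	6.981832712	376.1160276
W2	65.51715335	44.82418782	1.461647306	360.3443434	3.745704945	364.0900484
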