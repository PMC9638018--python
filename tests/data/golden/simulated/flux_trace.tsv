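# immetab 0.1.0 config_sha256=aed6c506bf408ec1
well	cycle_index	phase	injection	ocr	ecar
W1	1	basal		99.00628288	15.62653234
W1	2	basal		97.32025419	15.45643306
W1	3	basal		102.2872958	15.68808569
W1	4	glucose	glucose	104.3192376	63.39402812
W1	5	glucose		107.8215458	60.35611376
W1	6	glucose		104.0662589	62.98268411
W1	7	oligomycin	oligomycin	36.25265479	81.13902632
W1	8	oligomycin		39.93136227	78.02635615
W1	9	oligomycin		38.67710077	80.6710425
W1	10	bam15	bam15	159.9291199	72.19835478
W1	11	bam15		159.693054	72.39587078
W1	12	bam15		159.8250304	68.71793309
W1	13	rotenone_antimycin	rotenone_antimycin	15.07965433	39.41960498
W1	14	rotenone_antimycin		15.3551073	39.55072716
W1	15	rotenone_antimycin		13.98977599	39.85202447
W2	1	basal		99.39107968	14.81265437
W2	2	basal		102.3977324	11.44883238
W2	3	basal		96.18102532	15.80382963
W2	4	glucose	glucose	102.6412383	60.05310942
W2	5	glucose		107.9632047	58.50827476
W2	6	glucose		108.7890536	57.97649565
W2	7	oligomycin	oligomycin	40.97103349	79.62531772
W2	8	oligomycin		40.19265969	78.28370298
W2	9	oligomycin		41.67834338	77.66075752
W2	10	bam15	bam15	159.7934622	68.77303202
W2	11	bam15		161.6251683	68.24767948
W2	12	bam15		160.4373581	68.71163202
W2	13	rotenone_antimycin	rotenone_antimycin	16.19776626	39.23880195
W2	14	rotenone_antimycin		17.76553371	39.49090072
W2	15	rotenone_antimycin		14.44533598	43.9844504
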