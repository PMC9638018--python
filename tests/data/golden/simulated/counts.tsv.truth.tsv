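# immetab 0.1.0 config_sha256=aed6c506bf408ec1
gene_id	baseline_mean	log2_effect_group1	is_signature
IFNG_RESP_000	16.37720088	-1	True
IFNG_RESP_001	60.21755289	-1	True
IFNG_RESP_002	445.1866891	-1	True
IFNG_RESP_003	23.23912098	-1	True
IFNG_RESP_004	45.34743998	-1	True
IFNG_RESP_005	77.36732848	-1	True
IFNG_RESP_006	17.99294859	-1	True
IFNG_RESP_007	43.14624364	-1	True
IFNG_RESP_008	86.46040253	-1	True
IFNG_RESP_009	341.4706245	-1	True
IFNG_RESP_010	197.3349046	-1	True
IFNG_RESP_011	20.43737986	-1	True
IFNG_RESP_012	33.18629819	-1	True
IFNG_RESP_013	9.159580448	-1	True
IFNG_RESP_014	151.3991989	-1	True
IFNG_RESP_015	224.3410711	-1	True
IFNG_RESP_016	186.0610908	-1	True
IFNG_RESP_017	239.6602142	-1	True
IFNG_RESP_018	229.8831569	-1	True
IFNG_RESP_019	5.149453883	-1	True
IFNG_RESP_020	33.42205899	-1	True
IFNG_RESP_021	311.0141196	-1	True
IFNG_RESP_022	364.1290751	-1	True
IFNG_RESP_023	30.20874535	-1	True
IFNG_RESP_024	211.1423671	-1	True
IFNG_RESP_025	625.7790702	-1	True
IFNG_RESP_026	1833.356745	-1	True
IFNG_RESP_027	17.45354171	-1	True
IFNG_RESP_028	11.86271488	-1	True
IFNG_RESP_029	349.6319151	-1	True
IFNG_RESP_030	904.0565471	-1	True
IFNG_RESP_031	153.6922586	-1	True
IFNG_RESP_032	6.955578121	-1	True
IFNG_RESP_033	206.0859794	-1	True
IFNG_RESP_034	40.22812494	-1	True
IFNG_RESP_035	10.84936072	-1	True
IFNG_RESP_036	152.1172354	-1	True
IFNG_RESP_037	119.7587525	-1	True
IFNG_RESP_038	257.9993061	-1	True
IFNG_RESP_039	3.72975224	-1	True
IFNG_RESP_040	6.291568368	-1	True
IFNG_RESP_041	64.66814986	-1	True
IFNG_RESP_042	38.20696753	-1	True
IFNG_RESP_043	43.41580391	-1	True
IFNG_RESP_044	9.926657222	-1	True
GENE_00000	89.13551711	0	False
GENE_00001	18.50236064	0	False
GENE_00002	17.09807323	0	False
GENE_00003	56.65668464	0	False
GENE_00004	368.4775951	0	False
GENE_00005	127.8003854	0	False
GENE_00006	168.0831535	0	False
GENE_00007	605.1317164	0	False
GENE_00008	36.04900201	0	False
GENE_00009	11.63276198	0	False
GENE_00010	101.9747237	0	False
GENE_00011	215.2769044	0	False
GENE_00012	70.01176609	0	False
GENE_00013	310.7903822	0	False
GENE_00014	879.9777311	0	False
GENE_00015	183.4834278	0	False
GENE_00016	108.6596186	0	False
GENE_00017	716.6369512	0	False
GENE_00018	33.38091278	0	False
GENE_00019	49.98071368	0	False
GENE_00020	129.1146804	0	False
GENE_00021	44.75132156	0	False
GENE_00022	141.5161307	0	False
GENE_00023	20.55601022	0	False
GENE_00024	27.52616537	0	False
GENE_00025	182.7357996	0	False
GENE_00026	292.9493122	0	False
GENE_00027	122.1012918	0	False
GENE_00028	14.53241954	0	False
GENE_00029	95.86291118	0	False
GENE_00030	15.66177064	0	False
GENE_00031	32.10586223	0	False
GENE_00032	145.2451084	0	False
GENE_00033	36.77334572	0	False
GENE_00034	357.8763688	0	False
GENE_00035	47.93732371	0	False
GENE_00036	43.93134096	0	False
GENE_00037	23.52149225	0	False
GENE_00038	31.84562464	0	False
GENE_00039	156.6455855	0	False
GENE_00040	16.82620199	0	False
GENE_00041	168.8372165	0	False
GENE_00042	29.04538763	0	False
GENE_00043	57.07147675	0	False
GENE_00044	424.2560967	0	False
GENE_00045	400.5747687	0	False
GENE_00046	16.02375847	0	False
GENE_00047	35.56755221	0	False
GENE_00048	18.7707302	0	False
GENE_00049	27.17985013	0	False
GENE_00050	10.1255239	0	False
GENE_00051	174.6008202	0	False
GENE_00052	260.9809	0	False
GENE_00053	391.438731	0	False
GENE_00054	280.0630563	0	False
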