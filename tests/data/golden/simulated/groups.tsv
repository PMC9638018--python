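# immetab 0.1.0 config_sha256=aed6c506bf408ec1
sample	group
T000	SDHB_D
T001	SDHB_D
T002	SDHB_D
T003	SDHB_D
T004	SDHB_D
T005	SDHB_D
T006	SDHB_D
T007	SDHB_D
T008	SDHB_D
T009	SDHB_D
T010	SDHB_D
T011	SDHB_D
T012	SDHB_D
T013	SDHB_D
T014	SDHB_D
T015	SDHB_D
T016	SDHB_D
T017	SDHB_D
T018	other
T019	other
T020	other
T021	other
T022	other
T023	other
T024	other
T025	other
T026	other
T027	other
T028	other
T029	other
T030	other
T031	other
T032	other
T033	other
T034	other
T035	other
T036	other
T037	other
T038	other
T039	other
T040	other
T041	other
T042	other
T043	other
T044	other
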