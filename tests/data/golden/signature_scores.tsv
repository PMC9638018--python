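# immetab 0.1.0 config_sha256=aed6c506bf408ec1
sample	score	group
T000	4.544680812	SDHB_D
T001	4.957083973	SDHB_D
T002	4.699437524	SDHB_D
T003	4.881989143	SDHB_D
T004	4.773778544	SDHB_D
T005	4.665930893	SDHB_D
T006	4.851501432	SDHB_D
T007	4.855708395	SDHB_D
T008	0	SDHB_D
T009	0	SDHB_D
T010	0	SDHB_D
T011	5.037280711	SDHB_D
T012	0	SDHB_D
T013	0	SDHB_D
T014	4.84556326	SDHB_D
T015	4.751076542	SDHB_D
T016	4.823793663	SDHB_D
T017	4.809633161	SDHB_D
T018	5.360773672	other
T019	5.357196449	other
T020	5.276232932	other
T021	5.351820708	other
T022	5.346400623	other
T023	5.473306659	other
T024	5.444931377	other
T025	5.324244237	other
T026	5.413107394	other
T027	5.451823024	other
T028	5.43282197	other
T029	5.478402008	other
T030	5.503681308	other
T031	5.420783391	other
T032	5.303032225	other
T033	5.229482578	other
T034	5.549743478	other
T035	5.575047752	other
T036	5.179665643	other
T037	5.482895873	other
T038	5.454558509	other
T039	5.441460361	other
T040	5.547749314	other
T041	5.419177065	other
T042	0	other
T043	5.31214323	other
T044	5.446016104	other
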