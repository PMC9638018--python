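IFNG_RESP_000
IFNG_RESP_001
IFNG_RESP_002
IFNG_RESP_003
IFNG_RESP_004
IFNG_RESP_005
IFNG_RESP_006
IFNG_RESP_007
IFNG_RESP_008
IFNG_RESP_009
IFNG_RESP_010
IFNG_RESP_011
IFNG_RESP_012
IFNG_RESP_013
IFNG_RESP_014
IFNG_RESP_015
IFNG_RESP_016
IFNG_RESP_017
IFNG_RESP_018
IFNG_RESP_019
IFNG_RESP_020
IFNG_RESP_021
IFNG_RESP_022
IFNG_RESP_023
IFNG_RESP_024
IFNG_RESP_025
IFNG_RESP_026
IFNG_RESP_027
IFNG_RESP_028
IFNG_RESP_029
IFNG_RESP_030
IFNG_RESP_031
IFNG_RESP_032
IFNG_RESP_033
IFNG_RESP_034
IFNG_RESP_035
IFNG_RESP_036
IFNG_RESP_037
IFNG_RESP_038
IFNG_RESP_039
IFNG_RESP_040
IFNG_RESP_041
IFNG_RESP_042
IFNG_RESP_043
IFNG_RESP_044
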