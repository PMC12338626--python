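CVX Code	CVX Short Description	Full Vaccine Name	Status	VO Code
999	unknown	unknown vaccine or immune globulin	Inactive	VO_0010150
801	AS03	AS03 Adjuvant	Active	VO_0001320
998	no vaccine administered	no vaccine administered	Inactive	VO_0010149
99	RESERVED - do not use	RESERVED - do not use	Inactive	VO_0010229
98	TST, unspecified	tuberculin skin test; unspecified formulation	Inactive	VO_0010233
95	TST OT tine test	tuberculin skin test; old tuberculin, multipuncture device	Inactive	VO_0010230
96	TST PPD intradermal	tuberculin skin test; purified protein derivative solution, intradermal	Inactive	VO_0010231
97	TST PPD tine test	tuberculin skin test; purified protein derivative, multipuncture device	Inactive	VO_0010232
131	Historical typhus	Historical record of a typhus vaccination	Inactive	VO_0006019
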