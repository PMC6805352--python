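pair_id	left	right	origin_hpf	symmetry_class	verified
1	1d-112111	1c-1121121	9.9	NON_CORRESPONDING	false
2	1d-112112	1c-1121122	9.9	NON_CORRESPONDING	false
3	1d-112121	1c-1121111	11.2	NON_CORRESPONDING	false
4	1d-1122	1c-1122	6.0	QUADRANT_HOMOLOG_ABCD	true
5	1d-1121221	1c-1121112	11.5	NON_CORRESPONDING	false
6	1a-1211	1c-1211	8.5	AC_HOMOLOG	true
7	1a-112111	1b-1121121	9.2	NON_CORRESPONDING	false
8	1a-1121122	1b-1121111	10.2	NON_CORRESPONDING	false
9	1a-1122	1b-1122	6.0	QUADRANT_HOMOLOG_ABCD	true
10	1a-1121211	1a-1121121	10.4	SINGLE_QUADRANT	true
11	1b-12111aa	1b-121121b	13.0	SINGLE_QUADRANT	true
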