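mother	time_hpf	mode	suffix1	suffix2	fate1	fate2
1a	3.0	spiral_cw	1	2	none	none
1b	3.0	spiral_cw	1	2	none	none
1c	3.0	spiral_cw	1	2	none	none
1d	3.0	spiral_cw	1	2	none	none
1a-1	4.0	spiral_ccw	1	2	none	none
1b-1	4.0	spiral_ccw	1	2	none	none
1c-1	4.0	spiral_ccw	1	2	none	none
1d-1	4.0	spiral_ccw	1	2	none	none
1a-2	4.5	spiral_ccw	1	2	none	none
1b-2	4.5	spiral_ccw	1	2	none	none
1c-2	4.5	spiral_ccw	1	2	none	none
1d-2	4.5	spiral_ccw	1	2	none	none
1a-11	5.0	spiral_cw	1	2	apical_organ	none
1b-11	5.0	spiral_cw	1	2	apical_organ+b111_variable	none
1c-11	5.0	spiral_cw	1	2	apical_organ	none
1d-11	5.0	spiral_cw	1	2	apical_organ	none
1a-22	7.0	radial	1	2	primary_prototroch	primary_prototroch
1b-22	7.0	radial	1	2	primary_prototroch	primary_prototroch
1c-22	7.0	radial	1	2	primary_prototroch	primary_prototroch
1d-22	7.0	radial	1	2	primary_prototroch	primary_prototroch
1a-21	7.0	radial	1	2	accessory_prototroch	primary_prototroch
1b-21	7.0	radial	1	2	accessory_prototroch	primary_prototroch
1c-21	7.0	radial	1	2	accessory_prototroch	primary_prototroch
1d-21	6.5	radial	1	2	accessory_prototroch	primary_prototroch
1a-12	7.0	spiral_cw	1	2	none	accessory_prototroch
1b-12	7.0	spiral_cw	1	2	none	accessory_prototroch
1c-12	7.0	spiral_cw	1	2	none	accessory_prototroch
1d-12	7.0	spiral_cw	1	2	migrates_out	none
1a-121	8.5	spiral_ccw	1	2	none	accessory_prototroch
1b-121	8.5	spiral_ccw	1	2	none	accessory_prototroch
1c-121	8.5	spiral_ccw	1	2	none	accessory_prototroch
1d-122	8.5	spiral_ccw	1	2	accessory_prototroch	migrates_out
1a-112	6.0	bilateral	1	2	none	none
1b-112	6.0	bilateral	1	2	none	none
1c-112	6.0	bilateral	1	2	none	none
1d-112	6.0	bilateral	1	2	none	none
1a-1121	8.0	bilateral	1	2	none	none
1b-1121	8.0	bilateral	1	2	none	none
1c-1121	8.0	bilateral	1	2	none	none
1d-1121	8.0	bilateral	1	2	none	none
1a-111	9.0	budding	1	2	apical_organ	apical_organ+terminal
1a-1111	12.0	radial	1	2	apical_organ+terminal	grow:rosette_slow
1c-111	9.0	radial	1	2	apical_organ+terminal	apical_organ+terminal
1d-111	10.0	radial	1	2	apical_organ+terminal	apical_organ+terminal
1c-1122	7.0	bilateral	1	2	terminal	grow:otx_fast
1d-1122	7.0	bilateral	1	2	terminal	grow:otx_fast
1a-1122	7.0	bilateral	1	2	none	grow:vent_fast
1b-1122	7.0	bilateral	1	2	none	grow:vent_fast
1a-11221	9.0	bilateral	1	2	none	none
1b-11221	9.0	bilateral	1	2	none	none
1a-112211	11.0	bilateral	1	2	none	apoptotic
1b-112211	11.0	bilateral	1	2	none	apoptotic
1a-112212	11.5	bilateral	1	2	terminal	none
1b-112212	11.5	bilateral	1	2	terminal	none
1a-1122111	13.0	bilateral	1	2	grow:gland_branch	none
1b-1122111	13.0	bilateral	1	2	grow:gland_branch	none
1a-11221112	15.5	bilateral	1	2	terminal	grow:gland_branch
1b-11221112	15.5	bilateral	1	2	terminal	grow:gland_branch
1a-1122122	13.5	bilateral	1	2	grow:gland_branch	terminal
1b-1122122	13.5	bilateral	1	2	grow:gland_branch	terminal
1c-11211	8.8	bilateral	1	2	none	none
1c-112112	10.8	bilateral	1	2	grow:medial	grow:medial
1d-11211	9.9	bilateral	1	2	grow:medial	grow:medial
1c-112111	11.5	bilateral	1	2	grow:medial	grow:medial
1d-11212	11.2	bilateral	1	2	grow:medial	none
1d-112122	12.3	bilateral	1	2	grow:medial	terminal
1c-11212	13.0	bilateral	1	2	terminal	terminal
1a-11211	9.2	bilateral	1	2	grow:medial	none
1a-112112	10.4	bilateral	1	2	grow:medial	grow:medial
1a-11212	9.6	bilateral	1	2	none	terminal
1a-112121	10.9	bilateral	1	2	grow:medial	terminal
1b-11211	8.6	bilateral	1	2	none	none
1b-112111	10.2	bilateral	1	2	grow:medial	terminal
1b-112112	9.8	bilateral	1	2	grow:medial	terminal
1b-11212	12.6	bilateral	1	2	terminal	terminal
1a-1211	10.5	bilateral	1	2	apoptotic	none
1c-1211	10.5	bilateral	1	2	apoptotic	none
1a-12112	12.0	bilateral	1	2	none	grow:eye_branch
1c-12112	12.0	bilateral	1	2	none	grow:eye_branch
1a-121121	16.0	bilateral	1	2	terminal	terminal
1c-121121	16.0	bilateral	1	2	terminal	terminal
1b-1211	10.5	bilateral	1	2	none	none
1b-12111	12.0	bilateral	a	b	none	terminal
1b-12111a	13.6	bilateral	a	b	grow:medial	terminal
1b-12112	11.0	bilateral	1	2	none	terminal
1b-121121	13.0	bilateral	a	b	terminal	grow:medial
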