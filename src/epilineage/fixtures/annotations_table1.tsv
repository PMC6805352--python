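index	cell_type	lineage	support_k	support_n	refs	last_division_hpf	rid	markers	multiplicity	variable_suffix	caveat
1	Posterior prototroch 1	1d-221	2	2	yes	7	r1365	none	1
2	Posterior prototroch 2	1d-222	2	2	yes	7	r1366	none	1
3	Posterior prototroch 3	1d-212	2	2	yes	6.5	r1363	none	1
4	Posterior prototroch 4	1a-221	2	2	yes	7	r215	none	1
5	Posterior prototroch 5	1a-222	2	2	yes	7	r216	none	1
6	Posterior prototroch 6	1a-212	2	2	yes	7	r213	none	1
7	Posterior prototroch 7	1b-221	2	2	yes	7	r361	none	1
8	Posterior prototroch 8	1b-222	2	2	yes	7	r362	none	1
9	Posterior prototroch 9	1b-212	2	2	yes	7	r359	none	1
10	Posterior prototroch 10	1c-221	2	2	yes	7	r899	none	1
11	Posterior prototroch 11	1c-222	2	2	yes	7	r900	none	1
12	Posterior prototroch 12	1c-212	2	2	yes	7	r897	none	1
13	Anterior prototroch 1	1d-1221	3	3	no	8.5	r1356	none	1
14	Anterior prototroch 2	1d-211	2	2	yes	6.5	r1362	none	1
15	Anterior prototroch 3	1a-1212	3	3	no	8.5	r208	none	1
16	Anterior prototroch 4	1a-122	3	3	no	7	r209	none	1
17	Anterior prototroch 5	1a-211	2	2	yes	7	r212	none	1
18	Anterior prototroch 6	1b-1212	3	3	no	8.5	r354	none	1
19	Anterior prototroch 7	1b-122	3	3	no	7	r355	none	1
20	Anterior prototroch 8	1b-211	2	2	yes	7	r358	none	1
21	Anterior prototroch 9	1c-1212	3	3	no	8.5	r892	none	1
22	Anterior prototroch 10	1c-122	3	3	no	7	r893	none	1
23	Anterior prototroch 11-12	1c-211	2	2	yes	7	r896	none	2		one printed row covers two cells
24	Left head kidney	1d-11,221	5	5	no	7	r1133	none	1
25	Right head kidney	1c-11221	5	5	no	7	r613	none	1
26	Dorsally migrating 1st wave	1d-1222	5	5	no	8.5	r1357	none	1
27	Dorsally migrating 2nd wave	1d-121	5	5	no	7	r1352	none	1
28	Gland most right (GRR)	1b-112211121	3	4	no	15.5	r267	none	1
29	Gland middle right (GMR)	1b-11221222	3	3	no	13.5	r295	none	1
30	Gland middle (GMM)	1b-121122	3	3	no	13	r353	none	1
31	Gland middle left (GML)	1a-11221222	3	3	no	13.5	r126	none	1
32	Gland most left (GLL)	1a-112211121	3	3	no	15.5	r118	none	1
33	Apoptotic upper right	1c-12111	3	3	no	10.5	r838	none	1
34	Apoptotic lower right	1b-1122112	3	3	no	11	r290	none	1
35	Apoptotic upper left	1a-12111	3	3	no	10.5	r158	none	1
36	Apoptotic lower left	1a-1122112	3	3	no	11	r122	none	1
37	Ampullary cell right	1c-1112	3	3	no	9	r367	none	1
38	Ampullary cell left	1c-1111	3	3	no	9	r366	none	1
39	Large dorsal apical cell	1d-1112	5	5	no	10	r905	none	1
40	Crescent cell	1c-112121222	4	4	no	17.5	r574	none	1
41	First axon apical organ	1d-1111	3	3	no	10	r904	none	1
42	Larval eye pigment cell right	1c-121121b	3	3	no	16	r842	none	1
43	Larval eye photoreceptor right, chat+	1c-121121a	3	3	no	16	r841	chat	1
44	Larval eye pigment cell left	1a-1211211	3	3	no	16	r206	none	1
45	Larval eye photoreceptor left, chat+	1a-1211212	3	3	no	16	r207	chat	1
46	chat+ apical dorsal, phc2+, first bilateral axons	1a-11111	3	3	no	11.5	r5	chat,phc2	1
47	chat+ apical ventral peripheral (AVP)	1a-11212112b	3	3	no	16.5	r86	chat	1
48	chat+ apical ventral medial (AVM)	1a-11211212b	3	3	no	18	r50	chat	1
49	chat+ right lateral bigger (RLP)	1c-112112222ba	4	5	no	20	r525	chat	1
50	chat+ right lateral ventral (RLV)	1b-11211221	3	4	no	16.5	r241	chat	1
51	chat+ left lateral bigger (LLP)	1d-112112222aa	3	3	no	20	r1113	chat	1
52	chat+ left lateral ventral (LLV)	1d-112112221	2	2	no	28.5	r1125/r1121	chat	1	nn	terminal lineage varies between embryos
53	The right apical cell with axon, 5HT+, phc2+	1b-1121111	1	1	no	14.8	r226	5HT,phc2	1
54	The most dorsal serotonergic, 5HT+	1c-112122122a	1	1	no	17.5	r583	5HT	1
55	Asymmetric serotonergic, 5HT+	1c-112222211bb	1	1	no	22	r834	5HT	1
56	phc2+ close to the right apical cell with axon, more dorsal	1b-1121112	1	1	no	14.8	r227	phc2	1
57	phc2+	1a-1122121	1	1	no	11.5	r124	phc2	1
58	phc2+	1a-11112b	1	1	no	15.6	r24	phc2	1
59	phc2+, close to the right apical cell with axon, more ventral	1b-1122121	1	1	no	11.5	r292	phc2	1
60	phc2+ close to the crescent cell, more ventral	1d-112121	1	1	no	10	r1128	phc2	1
61	phc2+ close to the crescent cell, more dorsal	1d-1121221	1	1	no	15.2	r1130	phc2	1
62	Dorsal medial phc2+	1d-1121222	1	1	no	15.2	r1131	phc2	1
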