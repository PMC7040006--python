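mirna	direction	cpm_native	cpm_d3	cpm_d7	cpm_d14	log2fc_d3	log2fc_d7	log2fc_d14	sig_d3	sig_d7	sig_d14	transfection_candidate
hsa-miR-222-3p	down	18723	6440	6377	4381	-1.5	-1.6	-2.1	0	1	1	0
hsa-miR-221-5p	down	4066	566	403	594	-2.8	-3.3	-2.8	1	1	1	1
hsa-miR-484	down	2156	530	265	1385	-2.0	-3.0	-0.6	0	1	0	0
hsa-miR-24-2-5p	down	1096	285	167	310	-1.9	-2.7	-1.8	1	1	1	0
hsa-miR-335-5p	down	1078	252	189	203	-2.1	-2.5	-2.4	0	1	1	0
hsa-miR-335-3p	down	284	119	49	34	-1.3	-2.5	-3.1	0	0	1	0
hsa-miR-27a-5p	down	281	43	61	67	-2.7	-2.2	-2.1	1	1	1	1
hsa-miR-431-5p	down	231	82	73	48	-1.5	-1.7	-2.3	0	0	1	0
hsa-miR-222-5p	down	210	25	24	18	-3.1	-3.1	-3.6	1	1	1	0
hsa-miR-138-1-3p	down	203	52	42	13	-2.0	-2.3	-3.9	1	1	1	0
hsa-miR-17-5p	down	149	99	64	47	-0.6	-1.2	-1.7	0	0	1	0
hsa-miR-1185-1-3p	down	104	37	55	22	-1.5	-0.9	-2.2	0	0	1	0
hsa-miR-424-5p	down	101	41	21	21	-1.3	-2.3	-2.3	0	1	1	0
hsa-miR-146a-5p	up	7218	57295	60493	55211	3.0	3.1	2.9	1	1	1	0
hsa-miR-191-5p	up	15298	29437	45496	47388	0.9	1.6	1.6	0	1	1	0
hsa-let-7i-5p	up	24212	43439	76470	44284	0.8	1.7	0.9	0	1	0	0
hsa-miR-34a-5p	up	522	5372	5849	8076	3.4	3.5	4.0	1	1	1	1
hsa-miR-23b-3p	up	2178	2675	3652	5662	0.3	0.7	1.4	0	0	1	0
hsa-miR-132-3p	up	187	523	1278	706	1.5	2.8	1.9	0	1	1	0
hsa-miR-7706	up	91	267	303	430	1.6	1.7	2.2	0	0	1	0
hsa-miR-425-5p	up	203	277	1020	412	0.5	2.3	1.0	0	1	0	0
hsa-miR-328-3p	up	61	109	231	312	0.8	1.9	2.3	0	1	0	0
hsa-miR-212-5p	up	24	117	155	156	2.3	2.7	2.7	1	1	1	0
hsa-miR-1180-3p	up	55	85	285	155	0.6	2.4	1.5	0	1	0	0
hsa-miR-212-3p	up	48	171	243	153	1.8	2.3	1.7	0	1	0	0
hsa-miR-182-5p	up	43	87	188	144	1.0	2.1	1.7	0	1	0	0
hsa-miR-3605-3p	up	25	57	101	144	1.2	2.0	2.5	0	1	1	0
hsa-miR-132-5p	up	21	57	171	60	1.5	3.0	1.5	0	1	0	0
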