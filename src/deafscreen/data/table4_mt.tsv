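# Mitochondrial 12S rRNA variants: homo/heteroplasmy as reported, carrier
# counts in cases (N=658) and controls (N=462), conservation index as
# matching-species count over species compared (22 primates including the
# human reference), and catalogued population frequencies (Chinese
# reference panel N=1642; mtDB N=2704; -1 where no data was reported).
# The single "both" (hetero/homoplasmic) entries are treated as
# homoplasmic throughout the pipeline.
name	plasmy	case_count	case_freq	control_count	control_freq	ci_matches	ci_total	chinese_count	chinese_freq	previously_reported	mtdb_count	mtdb_freq
m.663A>G	homoplasmy	4	0.61	3	0.65	17	22	16	1.0	yes	86	3.2
m.681T>C	homoplasmy	9	1.37	6	1.30	18	22	30	1.8	yes	11	0.4
m.709G>A	homoplasmy	143	21.73	109	23.59	14	22	330	20.1	yes	444	16.4
m.735A>G	homoplasmy	4	0.61	2	0.43	16	22	10	0.6	yes	3	0.1
m.750A>G	homoplasmy	656	99.70	460	99.57	22	22	1638	99.8	yes	2682	96.7
m.752C>T	homoplasmy	16	2.43	15	3.25	22	22	51	3.1	yes	20	0.7
m.789T>C	homoplasmy	1	0.15	0	0.00	20	22	2	0.1	yes	1	0.0
m.827A>G	homoplasmy	24	3.65	13	2.81	20	22	54	3.3	yes	54	2.0
m.961insC	homoplasmy	15	2.28	1	0.22	20	22	25	1.5	yes	37	1.4
m.961delT+insC	both	2	0.30	0	0.00	20	22	1	0.1	yes	-1	-1
m.961T>C	homoplasmy	1	0.15	1	0.22	20	22	3	0.2	yes	37	1.4
m.979C>T	homoplasmy	1	0.15	0	0.00	6	22	0	0.0	yes	1	0.0
m.1005T>C	both	29	4.41	22	4.76	9	22	72	4.4	yes	7	0.3
m.1009C>T	homoplasmy	4	0.61	3	0.65	3	22	10	0.6	yes	2	0.1
m.1040T>C	homoplasmy	1	0.15	0	0.00	8	22	0	0.0	yes	2	0.1
m.1041A>G	homoplasmy	6	0.91	1	0.22	7	22	11	0.7	yes	14	0.5
m.1048C>T	homoplasmy	17	2.58	11	2.38	13	22	48	2.8	yes	51	1.9
m.1095T>C	homoplasmy	6	0.91	1	0.22	22	22	10	0.6	yes	5	0.2
m.1107T>C	homoplasmy	46	6.99	29	6.28	18	22	103	6.3	yes	34	1.3
m.1119T>C	homoplasmy	23	3.50	19	4.11	13	22	53	3.2	yes	26	1.0
m.1187T>C	homoplasmy	3	0.46	1	0.22	11	22	0	0.0	yes	1	0.0
m.1222A>G	homoplasmy	1	0.15	0	0.00	22	22	0	0.0	no	0	0.0
m.1282G>A	homoplasmy	2	0.30	0	0.00	13	22	0	0.0	yes	2	0.1
m.1382A>C	homoplasmy	17	2.58	11	2.38	17	22	43	2.6	yes	65	2.4
m.1415G>A	homoplasmy	1	0.15	0	0.00	8	22	1	0.1	yes	1	0.0
m.1438A>G	homoplasmy	658	100.00	461	99.78	22	22	1640	99.9	yes	2620	96.9
m.1494C>T	homoplasmy	4	0.61	0	0.00	18	22	3	0.2	yes	1	0.0
m.1520T>C	homoplasmy	3	0.46	0	0.00	6	22	6	0.4	yes	3	0.1
m.1555A>G	homoplasmy	39	5.93	0	0.00	20	22	65	4.0	yes	12	0.4
m.1598G>A	homoplasmy	14	2.13	10	2.16	22	22	49	3.0	yes	67	2.5
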