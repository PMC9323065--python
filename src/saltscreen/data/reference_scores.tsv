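accession	score_0.13	rank_0.13	score_0.17	rank_0.17	score_0.22	rank_0.22	total_score	total_rank
FM6	3.63	3	3.31	2	3.18	1	10.12	1
FM7	3.49	4	2.74	4	2.50	5	8.74	4
FM31	3.38	5	2.11	5	2.62	4	8.12	5
FM96	3.85	1	3.41	1	2.75	3	10.02	2
FM73	3.69	2	2.95	3	2.89	2	9.53	3
FM15	0.76	13	0.28	17	0.43	12	1.48	16
FM27	1.89	7	0.66	9	0.56	11	3.11	7
FM41	0.50	17	0.41	15	0.41	15	1.33	17
FM48	0.53	16	0.57	10	0.67	7	1.77	13
FM49	0.79	11	0.50	11	0.60	8	1.88	11
FM62	1.19	8	0.86	6	0.71	9	2.77	8
FM66	0.56	15	0.40	13	0.95	6	1.91	10
FM72	0.77	12	0.41	14	0.45	17	1.62	15
FM78	2.09	6	0.77	7	0.42	16	3.27	6
FM86	1.08	9	0.48	12	0.48	13	2.03	9
FM89	0.90	10	0.38	16	0.48	10	1.76	14
FM90	0.47	18	0.26	18	0.14	18	0.87	18
FM102	0.74	14	0.67	8	0.45	14	1.87	12
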