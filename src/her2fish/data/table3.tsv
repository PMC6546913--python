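image	ratio1	ratio2	her2_cen17	nd_call	sd_call	pathologist1	pathologist2	pathologist3
1	0.08	0.83	9.42	HIGH	HIGH	HIGH	HIGH	HIGH
2	0.07	0.93	9.43	HIGH	HIGH	HIGH	HIGH	HIGH
3	0	1.00	10.00	HIGH	HIGH	HIGH	HIGH	HIGH
4	0.13	0.88	7.75	HIGH	HIGH	HIGH	HIGH	HIGH
5	0.33	0.67	10.00	HIGH	HIGH	HIGH	HIGH	HIGH
6	0.07	0.93	9.69	HIGH	HIGH	HIGH	HIGH	HIGH
7	0.22	0.78	9.11	HIGH	HIGH	HIGH	HIGH	HIGH
8	0	0.91	9.13	HIGH	HIGH	HIGH	HIGH	HIGH
9	0.17	0.83	10.00	HIGH	HIGH	HIGH	HIGH	HIGH
10	0	1.00	10.00	HIGH	HIGH	HIGH	HIGH	HIGH
11	0	1.00	10.00	HIGH	HIGH	HIGH	HIGH	HIGH
12	0	1.00	10.00	HIGH	HIGH	HIGH	HIGH	HIGH
13	0.17	0.75	9.46	HIGH	HIGH	HIGH	HIGH	HIGH
14	0.25	0.75	9.15	HIGH	HIGH	HIGH	HIGH	HIGH
15	0.26	0.74	8.08	HIGH	HIGH	HIGH	HIGH	HIGH
16	0.57	0	2.63	LOW	LOW	LOW	LOW	LOW
17	0.75	0	3.67	LOW	LOW	LOW	LOW	LOW
18	0.67	0.17	1.40	LOW	LOW	LOW	LOW	LOW
19	0.31	0	3.37	LOW	LOW	LOW	LOW	LOW
20	0.36	0	1.55	LOW	LOW	LOW	LOW	LOW
21	0.40	0	4.33	LOW	LOW	LOW	LOW	LOW
22	0.40	0	1.65	LOW	LOW	LOW	LOW	LOW
23	0.31	0	1.65	LOW	LOW	LOW	LOW	LOW
24	0.33	0	1.93	LOW	LOW	LOW	LOW	LOW
25	0.50	0.10	1.67	LOW	LOW	LOW	LOW	LOW
26	0.50	0	4.89	LOW	LOW	LOW	LOW	LOW
27	0.44	0.22	3.33	LOW	LOW	LOW	LOW	LOW
28	0.27	0	1.00	LOW	NORMAL	LOW	LOW	LOW
29	0.25	0	3.43	LOW	LOW	LOW	LOW	LOW
30	0.15	0.69	8.71	HIGH	HIGH	HIGH	HIGH	HIGH
31	0	1.00	8.20	HIGH	HIGH	HIGH	HIGH	HIGH
32	0	1.00	9.00	HIGH	HIGH	HIGH	HIGH	HIGH
33	0.09	0.91	8.82	HIGH	HIGH	HIGH	HIGH	HIGH
34	0.05	0.95	8.93	HIGH	HIGH	HIGH	HIGH	HIGH
35	0	1.00	10.00	HIGH	HIGH	HIGH	HIGH	HIGH
36	0.15	0.85	9.43	HIGH	HIGH	HIGH	HIGH	HIGH
37	0.17	0.83	10.00	HIGH	HIGH	HIGH	HIGH	HIGH
38	0	1.00	10.00	HIGH	HIGH	HIGH	HIGH	HIGH
39	0	1.00	10.00	HIGH	HIGH	HIGH	HIGH	HIGH
40	0.15	0.85	9.41	HIGH	HIGH	HIGH	HIGH	HIGH
41	0	1.00	10.00	HIGH	HIGH	HIGH	HIGH	HIGH
42	0	1.00	10.00	HIGH	HIGH	HIGH	HIGH	HIGH
43	0	1.00	10.00	HIGH	HIGH	HIGH	HIGH	HIGH
44	0.29	0	1.35	LOW	LOW	LOW	LOW	LOW
45	0.44	0	1.63	LOW	LOW	LOW	LOW	LOW
46	0.56	0	1.92	LOW	LOW	LOW	LOW	LOW
47	0.67	0	5.63	LOW	LOW	LOW	LOW	LOW
48	1.00	0	4.50	LOW	LOW	LOW	LOW	LOW
49	0.53	0	3.20	LOW	LOW	LOW	LOW	LOW
50	0.69	0.06	1.91	LOW	LOW	LOW	LOW	LOW
51	0.38	0	2.44	LOW	LOW	LOW	LOW	LOW
52	0.40	0	2.81	LOW	LOW	LOW	LOW	LOW
53	0.67	0.17	4.93	LOW	LOW	LOW	LOW	LOW
54	1.00	0	1.17	LOW	LOW	LOW	LOW	LOW
55	0.40	0	7.00	LOW	HIGH	LOW	LOW	LOW
56	0.29	0	1.39	LOW	LOW	LOW	LOW	LOW
57	0.43	0	2.90	LOW	LOW	LOW	LOW	LOW
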