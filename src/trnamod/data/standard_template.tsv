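# Standard 76-column canonical tRNA numbering template
column_index	canonical_label	region
1	1	acceptor-stem
2	2	acceptor-stem
3	3	acceptor-stem
4	4	acceptor-stem
5	5	acceptor-stem
6	6	acceptor-stem
7	7	acceptor-stem
8	8	core
9	9	core
10	10	d-stem
11	11	d-stem
12	12	d-stem
13	13	d-stem
14	14	d-loop
15	15	d-loop
16	16	d-loop
17	17	d-loop
18	18	d-loop
19	19	d-loop
20	20	d-loop
21	21	d-loop
22	22	d-stem
23	23	d-stem
24	24	d-stem
25	25	d-stem
26	26	core
27	27	anticodon-stem
28	28	anticodon-stem
29	29	anticodon-stem
30	30	anticodon-stem
31	31	anticodon-stem
32	32	anticodon-loop
33	33	anticodon-loop
34	34	anticodon-loop
35	35	anticodon-loop
36	36	anticodon-loop
37	37	anticodon-loop
38	38	anticodon-loop
39	39	anticodon-stem
40	40	anticodon-stem
41	41	anticodon-stem
42	42	anticodon-stem
43	43	anticodon-stem
44	44	variable-loop
45	45	variable-loop
46	46	variable-loop
47	47	variable-loop
48	48	variable-loop
49	49	t-stem
50	50	t-stem
51	51	t-stem
52	52	t-stem
53	53	t-stem
54	54	t-loop
55	55	t-loop
56	56	t-loop
57	57	t-loop
58	58	t-loop
59	59	t-loop
60	60	t-loop
61	61	t-stem
62	62	t-stem
63	63	t-stem
64	64	t-stem
65	65	t-stem
66	66	acceptor-stem
67	67	acceptor-stem
68	68	acceptor-stem
69	69	acceptor-stem
70	70	acceptor-stem
71	71	acceptor-stem
72	72	acceptor-stem
73	73	ncca-end
74	74	ncca-end
75	75	ncca-end
76	76	ncca-end
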