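# energy_keV	mu_over_rho_cm2_g
10	27.1466
11	20.4501
12	15.8018
13	12.4749
14	10.0311
15	8.19584
16	6.79081
17	5.69694
18	4.83261
19	4.14061
20	3.58
21	3.121
22	2.74157
23	2.42516
24	2.15919
25	1.93398
26	1.742
27	1.57731
28	1.43523
29	1.31199
30	1.20455
31	1.11045
32	1.02767
33	0.954548
34	0.889708
35	0.831999
36	0.780461
37	0.734282
38	0.692775
39	0.65536
40	0.621536
41	0.590877
42	0.563017
43	0.537638
44	0.514464
45	0.493257
46	0.473808
47	0.455935
48	0.439477
49	0.424293
50	0.410258
51	0.397263
52	0.385211
53	0.374013
54	0.363593
55	0.353881
56	0.344817
57	0.336344
58	0.328413
59	0.320978
60	0.314
61	0.307442
62	0.301271
63	0.295456
64	0.289972
65	0.284792
66	0.279895
67	0.27526
68	0.270868
69	0.266702
70	0.262747
71	0.258987
72	0.255411
73	0.252005
74	0.248758
75	0.245661
76	0.242703
77	0.239877
78	0.237173
79	0.234584
80	0.232104
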