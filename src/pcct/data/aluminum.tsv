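# energy_keV	mu_over_rho_cm2_g
10	26.2902
11	19.7973
12	15.2905
13	12.0648
14	9.6954
15	7.91601
16	6.55379
17	5.49328
18	4.65533
19	3.98446
20	3.441
21	2.99605
22	2.62826
23	2.32157
24	2.06378
25	1.84552
26	1.65947
27	1.49989
28	1.36223
29	1.24282
30	1.13875
31	1.0476
32	0.967434
33	0.896629
34	0.833852
35	0.77799
36	0.728109
37	0.683423
38	0.643268
39	0.607078
40	0.574371
41	0.544732
42	0.517805
43	0.493283
44	0.470899
45	0.450421
46	0.431647
47	0.4144
48	0.398524
49	0.383883
50	0.370356
51	0.357837
52	0.34623
53	0.335452
54	0.325427
55	0.316089
56	0.307377
57	0.299238
58	0.291624
59	0.284491
60	0.2778
61	0.271515
62	0.265605
63	0.260041
64	0.254796
65	0.249846
66	0.245169
67	0.240746
68	0.236558
69	0.232588
70	0.228822
71	0.225246
72	0.221847
73	0.218612
74	0.215532
75	0.212595
76	0.209794
77	0.207119
78	0.204563
79	0.202118
80	0.199777
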