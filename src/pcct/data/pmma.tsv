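# energy_keV	mu_over_rho_cm2_g
10	3.16148
11	2.42667
12	1.91642
13	1.55102
14	1.28246
15	1.08061
16	0.925927
17	0.805366
18	0.709976
19	0.633482
20	0.5714
21	0.520462
22	0.478253
23	0.442959
24	0.4132
25	0.387915
26	0.366278
27	0.347639
28	0.331483
29	0.317397
30	0.305049
31	0.294168
32	0.284534
33	0.275963
34	0.268305
35	0.261433
36	0.255242
37	0.249644
38	0.244563
39	0.239934
40	0.235704
41	0.231825
42	0.228257
43	0.224966
44	0.22192
45	0.219094
46	0.216466
47	0.214014
48	0.211721
49	0.209572
50	0.207553
51	0.205651
52	0.203857
53	0.20216
54	0.200553
55	0.199026
56	0.197575
57	0.196191
58	0.194871
59	0.193609
60	0.1924
61	0.191241
62	0.190127
63	0.189056
64	0.188025
65	0.18703
66	0.186069
67	0.185141
68	0.184242
69	0.183371
70	0.182526
71	0.181706
72	0.180909
73	0.180133
74	0.179378
75	0.178642
76	0.177925
77	0.177225
78	0.176541
79	0.175872
80	0.175218
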