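# energy_keV	mu_over_rho_cm2_g
10	3.00351
11	2.30751
12	1.82419
13	1.47807
14	1.22367
15	1.03245
16	0.885914
17	0.771694
18	0.681313
19	0.608832
20	0.55
21	0.501724
22	0.461716
23	0.428257
24	0.400041
25	0.376064
26	0.355541
27	0.337858
28	0.322527
29	0.309157
30	0.297434
31	0.287101
32	0.277948
33	0.269803
34	0.262522
35	0.255987
36	0.250097
37	0.244768
38	0.239929
39	0.235519
40	0.231487
41	0.227787
42	0.224383
43	0.22124
44	0.218331
45	0.21563
46	0.213116
47	0.210769
48	0.208573
49	0.206514
50	0.204578
51	0.202754
52	0.201031
53	0.199401
54	0.197855
55	0.196387
56	0.19499
57	0.193657
58	0.192384
59	0.191167
60	0.19
61	0.18888
62	0.187804
63	0.186768
64	0.18577
65	0.184807
66	0.183876
67	0.182976
68	0.182104
69	0.181259
70	0.180439
71	0.179642
72	0.178867
73	0.178112
74	0.177378
75	0.176661
76	0.175962
77	0.17528
78	0.174613
79	0.173961
80	0.173323
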