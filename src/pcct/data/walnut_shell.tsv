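# energy_keV	mu_over_rho_cm2_g
10	8.15473
11	6.17947
12	4.80822
13	3.82661
14	3.10544
15	2.56371
16	2.14887
17	1.82578
18	1.57039
19	1.36582
20	1.2
21	1.06415
22	0.951764
23	0.85797
24	0.779055
25	0.712164
26	0.655074
27	0.606039
28	0.563673
29	0.526866
30	0.494724
31	0.46652
32	0.441658
33	0.419648
34	0.400084
35	0.382627
36	0.366993
37	0.352943
38	0.340275
39	0.328817
40	0.318422
41	0.308963
42	0.300334
43	0.292439
44	0.285198
45	0.278541
46	0.272405
47	0.266737
48	0.26149
49	0.256621
50	0.252095
51	0.247879
52	0.243943
53	0.240263
54	0.236815
55	0.233579
56	0.230536
57	0.227671
58	0.224969
59	0.222416
60	0.22
61	0.217711
62	0.215539
63	0.213474
64	0.21151
65	0.209638
66	0.207852
67	0.206147
68	0.204515
69	0.202952
70	0.201454
71	0.200017
72	0.198635
73	0.197307
74	0.196027
75	0.194795
76	0.193605
77	0.192457
78	0.191347
79	0.190273
80	0.189234
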