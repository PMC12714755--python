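# energy_keV	mu_over_rho_cm2_g
10	5.02857
11	3.83085
12	2.99928
13	2.40392
14	1.96644
15	1.63775
16	1.38597
17	1.18982
18	1.03471
19	0.910406
20	0.8096
21	0.726963
22	0.658554
23	0.601417
24	0.553302
25	0.512479
26	0.4776
27	0.447606
28	0.421657
29	0.399081
30	0.379335
31	0.361978
32	0.34665
33	0.333053
34	0.320941
35	0.310108
36	0.300382
37	0.291619
38	0.283696
39	0.276508
40	0.269966
41	0.263995
42	0.258528
43	0.253508
44	0.248887
45	0.244621
46	0.240674
47	0.237012
48	0.233606
49	0.230433
50	0.227468
51	0.224693
52	0.22209
53	0.219644
54	0.21734
55	0.215166
56	0.213112
57	0.211166
58	0.209321
59	0.207568
60	0.2059
61	0.20431
62	0.202793
63	0.201342
64	0.199954
65	0.198623
66	0.197346
67	0.196119
68	0.194938
69	0.193801
70	0.192704
71	0.191645
72	0.190621
73	0.189631
74	0.188673
75	0.187743
76	0.186842
77	0.185966
78	0.185116
79	0.184288
80	0.183483
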