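age,qx_male,qx_female
0,8.726566405337088e-05,8.726566405337088e-05
1,9.500725000965993e-05,9.500725000965993e-05
2,0.00010343557861414165,0.00010343557861414165
3,0.00011261156303232767,0.00011261156303232767
4,0.00012260151812748532,0.00012260151812748532
5,0.00013347763924964617,0.00013347763924964617
6,0.00014531852342125617,0.00014531852342125617
7,0.00015820973666613725,0.00015820973666613725
8,0.00017224443155661184,0.00017224443155661184
9,0.00018752401941424246,0.00018752401941424246
10,0.00020415890198821618,0.00020415890198821618
11,0.00022226926785728907,0.00022226926785728907
12,0.00024198595926427924,0.00024198595926427924
13,0.0002634514155891443,0.0002634514155891443
14,0.0002868207002123535,0.0002868207002123535
15,0.0003122626181064625,0.0003122626181064625
16,0.00033996093213961576,0.00033996093213961576
17,0.00037011568676359463,0.00037011568676359463
18,0.00040294464851953204,0.00040294464851953204
19,0.0004386848736097626,0.0004386848736097626
20,0.0004775944136726773,0.0004775944136726773
21,0.0005199541718625689,0.0005199541718625689
22,0.0005660699223783983,0.0005660699223783983
23,0.0006162745077152865,0.0006162745077152865
24,0.0006709302291427743,0.0006709302291427743
25,0.0007304314472308393,0.0007304314472308393
26,0.0007952074106893914,0.0007952074106893914
27,0.000865725333327183,0.000865725333327183
28,0.0009424937406206091,0.0009424937406206091
29,0.0010260661091863188,0.0010260661091863188
30,0.001117044824404112,0.001117044824404112
31,0.0012160854835432389,0.0012160854835432389
32,0.001323901574005748,0.001323901574005748
33,0.0014412695587395774,0.0014412695587395774
34,0.0015690344034913206,0.0015690344034913206
35,0.001708115583375136,0.001708115583375136
36,0.0018595136092423026,0.0018595136092423026
37,0.0020243171175525765,0.0020243171175525765
38,0.002203710570880424,0.002203710570880424
39,0.002398982619845391,0.002398982619845391
40,0.0026115351811384357,0.0026115351811384357
41,0.00284289329043097,0.00284289329043097
42,0.0030947157932983416,0.0030947157932983416
43,0.003368806941858815,0.003368806941858815
44,0.003667128969618738,0.003667128969618738
45,0.0039918157220077966,0.0039918157220077966
46,0.004345187425258135,0.004345187425258135
47,0.004729766681607184,0.004729766681607184
48,0.005148295784233037,0.005148295784233037
49,0.005603755450818704,0.005603755450818704
50,0.006099385080101882,0.006099385080101882
51,0.006638704641128368,0.006638704641128368
52,0.007225538310048463,0.007225538310048463
53,0.00786403997406715,0.00786403997406715
54,0.008558720726364766,0.008558720726364766
55,0.009314478479267363,0.009314478479267363
56,0.010136629825369448,0.010136629825369448
57,0.011030944277397148,0.011030944277397148
58,0.01200368101694882,0.01200368101694882
59,0.013061628279410709,0.013061628279410709
60,0.014212145496754869,0.014212145496754869
61,0.015463208310936616,0.015463208310936616
62,0.016823456557435557,0.016823456557435557
63,0.018302245300216846,0.018302245300216846
64,0.01990969897494066,0.01990969897494066
65,0.0216567686653667,0.0216567686653667
66,0.023555292497111413,0.023555292497111413
67,0.025618059081525146,0.025618059081525146
68,0.027858873878484958,0.027858873878484958
69,0.03029262826812218,0.03029262826812218
70,0.03293537102532007,0.03293537102532007
71,0.03580438177434975,0.03580438177434975
72,0.0389182458609697,0.0389182458609697
73,0.042296929912068904,0.042296929912068904
74,0.04596185715446344,0.04596185715446344
75,0.04993598133039845,0.04993598133039845
76,0.05424385777297469,0.05424385777297469
77,0.058911709885203,0.058911709885203
78,0.0639674888966425,0.0639674888966425
79,0.06944092434665472,0.06944092434665472
80,0.07536356225854979,0.07536356225854979
81,0.08176878742037486,0.08176878742037486
82,0.08869182557300648,0.08869182557300648
83,0.09616972062359441,0.09616972062359441
84,0.10424128125392862,0.10424128125392862
85,0.11294699048430656,0.11294699048430656
86,0.12232887089434274,0.12232887089434274
87,0.13243029730985734,0.13243029730985734
88,0.14329574786507127,0.14329574786507127
89,0.15497048347827613,0.15497048347827613
90,0.16750014498691912,0.16750014498691912
91,0.1809302565411679,0.1809302565411679
92,0.19530562343972113,0.19530562343972113
93,0.21066961251713312,0.21066961251713312
94,0.2270633035934585,0.2270633035934585
95,0.24452450153827665,0.24452450153827665
96,0.263086600375412,0.263086600375412
97,0.28277729378391947,0.28277729378391947
98,0.3036171305817612,0.3036171305817612
99,0.32561791957369957,0.32561791957369957
100,0.3487809957677964,0.3487809957677964
101,0.3730953696570374,0.3730953696570374
102,0.3985357932094564,0.3985357932094564
103,0.4250607904956545,0.4250607904956545
104,0.45261071742886605,0.45261071742886605
105,0.48110593358642584,0.48110593358642584
106,0.5104451888868549,0.5104451888868549
107,0.540504347961791,0.540504347961791
108,0.5711355938252531,0.5711355938252531
109,0.6021672677585382,0.6021672677585382
110,0.6334045114314513,0.6334045114314513
111,0.6646308768191704,0.6646308768191704
112,0.6956110556582598,0.6956110556582598
113,0.7260948490800682,0.7260948490800682
114,0.755822446072087,0.755822446072087
115,0.7845310039987776,0.7845310039987776
116,0.8119624249701,0.8119624249701
117,0.8378721008032559,0.8378721008032559
118,0.8620382632011132,0.8620382632011132
119,0.8842714360467124,0.8842714360467124
120,1.0,1.0
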