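age,sex,annual_qx,cv_share
40,male,0.0014639230461551299,0.45000000000000001
41,male,0.0015999352319068839,0.44750000000000001
42,male,0.0017849915809090026,0.44500000000000001
43,male,0.0019400296335359095,0.4425
44,male,0.0021041084919704704,0.44
45,male,0.0023533436501225885,0.4375
46,male,0.0026344784916857945,0.435
47,male,0.0028735461658234329,0.4325
48,male,0.0030542392417771658,0.42999999999999999
49,male,0.0033177830909983637,0.42749999999999999
50,male,0.0036918945570356908,0.42499999999999999
51,male,0.0041100359080465726,0.42249999999999999
52,male,0.0043064100850693588,0.42000000000000004
53,male,0.0049343917467716755,0.41749999999999998
54,male,0.0053105054905792665,0.41500000000000004
55,male,0.0058941474356829079,0.41250000000000003
56,male,0.0064994663009009281,0.41000000000000003
57,male,0.007172679125621243,0.40750000000000003
58,male,0.0079951719749039273,0.40500000000000003
59,male,0.0088946992820790605,0.40250000000000002
60,male,0.0095451631750542425,0.40000000000000002
61,male,0.010804195328520344,0.39750000000000002
62,male,0.011396443717922415,0.39500000000000002
63,male,0.012776856482216964,0.39250000000000002
64,male,0.014191946406849277,0.39000000000000001
65,male,0.015340332814883329,0.38750000000000001
66,male,0.016572343647710666,0.38500000000000001
67,male,0.018140930486536352,0.38250000000000001
68,male,0.020114696742892207,0.38
69,male,0.022398839469094708,0.3775
70,male,0.024008618785969216,0.375
71,male,0.026800531894688229,0.3725
72,male,0.029471413081657721,0.37
73,male,0.032832607653037589,0.36749999999999999
74,male,0.03583404531951942,0.36499999999999999
75,male,0.039476781928813827,0.36249999999999999
76,male,0.042501045407256834,0.35999999999999999
77,male,0.047182024017320447,0.35750000000000004
78,male,0.052788045549764351,0.35499999999999998
79,male,0.058819525642881336,0.35250000000000004
80,male,0.061155752825901327,0.34999999999999998
81,male,0.071014474405422648,0.34750000000000003
82,male,0.077751881809935627,0.34500000000000003
83,male,0.084456066294661736,0.34250000000000003
84,male,0.09182589681644468,0.34000000000000002
85,male,0.099716064197873475,0.33750000000000002
86,male,0.11349578041894268,0.33500000000000002
87,male,0.12594060563462797,0.33250000000000002
88,male,0.13791505374181032,0.33000000000000002
89,male,0.15004080957526647,0.32750000000000001
90,male,0.1617016311188387,0.32500000000000001
91,male,0.17216251286827464,0.32250000000000001
92,male,0.19373982737258022,0.32000000000000001
93,male,0.21566682593715431,0.3175
94,male,0.2278842936977199,0.315
95,male,0.25891703620124212,0.3125
96,male,0.2846335374966325,0.31
97,male,0.31435599951634302,0.3075
98,male,0.33259411953100643,0.30500000000000005
99,male,0.36921206992292149,0.30249999999999999
100,male,0.40743301577016022,0.30000000000000004
40,female,0.0011126536614591001,0.45000000000000001
41,female,0.0012955447251346837,0.44750000000000001
42,female,0.0013610080953845728,0.44500000000000001
43,female,0.0015200196751084839,0.4425
44,female,0.0016503253254648686,0.44
45,female,0.0018810184218380282,0.4375
46,female,0.0020555657333127943,0.435
47,female,0.0022273464379444991,0.4325
48,female,0.0023119092278355742,0.42999999999999999
49,female,0.0026569649252888832,0.42749999999999999
50,female,0.0029559426750402885,0.42499999999999999
51,female,0.0032681468700130768,0.42249999999999999
52,female,0.0034756647143922904,0.42000000000000004
53,female,0.004009169503869643,0.41749999999999998
54,female,0.0041360253526373852,0.41500000000000004
55,female,0.0046039439928629074,0.41250000000000003
56,female,0.0052218141827226712,0.41000000000000003
57,female,0.0056357203744049917,0.40750000000000003
58,female,0.0064378313596473785,0.40500000000000003
59,female,0.0068203737348532818,0.40250000000000002
60,female,0.0073704591529973867,0.40000000000000002
61,female,0.008138391989649189,0.39750000000000002
62,female,0.0088138201747577742,0.39500000000000002
63,female,0.0096464529999249864,0.39250000000000002
64,female,0.011009429316024182,0.39000000000000001
65,female,0.012082609683580343,0.38750000000000001
66,female,0.013464210118613309,0.38500000000000001
67,female,0.014197299500641837,0.38250000000000001
68,female,0.016377788144347424,0.38
69,female,0.017294631443848858,0.3775
70,female,0.019719974418008518,0.375
71,female,0.020811134779144425,0.3725
72,female,0.02272428600137805,0.37
73,female,0.025460789288463324,0.36749999999999999
74,female,0.02841090209338093,0.36499999999999999
75,female,0.030672426085088488,0.36249999999999999
76,female,0.033196130232042632,0.35999999999999999
77,female,0.035920906941879618,0.35750000000000004
78,female,0.03941370041133533,0.35499999999999998
79,female,0.044979082273509635,0.35250000000000004
80,female,0.049895865669042916,0.34999999999999998
81,female,0.053562971251644456,0.34750000000000003
82,female,0.057780802808574207,0.34500000000000003
83,female,0.0659966992484015,0.34250000000000003
84,female,0.069445064936178372,0.34000000000000002
85,female,0.077160103116446846,0.33750000000000002
86,female,0.087057101584234464,0.33500000000000002
87,female,0.090300325301016712,0.33250000000000002
88,female,0.1045715240850128,0.33000000000000002
89,female,0.1126753944793159,0.32750000000000001
90,female,0.12550297711032296,0.32500000000000001
91,female,0.13736338448521396,0.32250000000000001
92,female,0.15174267737371946,0.32000000000000001
93,female,0.16834699993925711,0.3175
94,female,0.17964388800820236,0.315
95,female,0.20614164442102506,0.3125
96,female,0.22333340890880538,0.31
97,female,0.24592301494635893,0.3075
98,female,0.27190185281973595,0.30500000000000005
99,female,0.29645506359193613,0.30249999999999999
100,female,0.32604175629119303,0.30000000000000004
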