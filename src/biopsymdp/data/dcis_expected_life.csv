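age,value
40,37.5750990796
41,36.6863355241
42,35.8014247069
43,34.9206337906
44,34.044240809
45,33.1725346952
46,32.3058152589
47,31.444393109
48,30.5885895157
49,29.7387362062
50,28.8951750901
51,28.0582579074
52,27.2283457956
53,26.4058087693
54,25.5910251087
55,24.7843806529
56,23.9862679929
57,23.1970855629
58,22.417236626
59,21.6471281538
60,20.8871695992
61,20.1377715629
62,19.3993443553
63,18.6722964581
64,17.9570328892
65,17.2539534786
66,16.5634510623
67,15.8859096053
68,15.221702264
69,14.5711894034
70,13.934716582
71,13.3126125239
72,12.7051870943
73,12.1127293001
74,11.5355053356
75,10.9737566963
76,10.4276983824
77,9.89751721662
78,9.38337029769
79,8.8853836131
80,8.40365083218
81,7.93823229974
82,7.48915424862
83,7.05640824698
84,6.63995089378
85,6.23970377225
86,5.85555366841
87,5.48735305704
88,5.13492085446
89,4.79804343267
90,4.47647588584
91,4.16994353581
92,3.87814365963
93,3.60074741851
94,3.33740196459
95,3.08773269897
96,2.85134565259
97,2.62782995984
98,2.41676039387
99,2.21769993238
100,2.030202323
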