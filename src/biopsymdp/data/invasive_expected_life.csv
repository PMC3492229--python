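age,value
40,31.2730754976
41,30.6459985581
42,30.0168028442
43,29.3857185951
44,28.7529897759
45,28.1188743483
46,27.4836444991
47,26.8475868205
48,26.2110024347
49,25.5742070586
50,24.9375309988
51,24.3013190731
52,23.665930449
53,23.0317383929
54,22.3991299245
55,21.7685053677
56,21.1402777928
57,20.5148723439
58,19.8927254465
59,19.2742838902
60,18.6600037829
61,18.050349375
62,17.4457917505
63,16.8468073873
64,16.2538765859
65,15.6674817721
66,15.0881056779
67,14.5162294077
68,13.9523303999
69,13.3968802946
70,12.8503427221
71,12.3131710276
72,11.7858059495
73,11.2686732731
74,10.7621814804
75,10.2667194195
76,9.78265402042
77,9.31032808099
78,8.85005815183
79,8.40213254611
80,7.96680950131
81,7.54431551916
82,7.13484390812
83,6.73855355155
84,6.35556792189
85,5.98597435846
86,5.62982362297
87,5.28712974309
88,4.95787015027
89,4.6419861134
90,4.3393834655
91,4.04993361577
92,3.77347483498
93,3.50981379746
94,3.25872735909
95,3.01996454688
96,2.79324873251
97,2.57827995976
98,2.37473739364
99,2.18228185795
100,2.00055842754
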