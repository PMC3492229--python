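age,value
40,0.00199331910812
41,0.0021725490224
42,0.00236789445077
43,0.00258080442474
44,0.00281285826596
45,0.00306577730127
46,0.00334143763116
47,0.00364188404627
48,0.00396934519525
49,0.0043262501164
50,0.00471524625573
51,0.00513921910523
52,0.00560131360678
53,0.00610495748071
54,0.00665388665191
55,0.00725217296211
56,0.00790425437399
57,0.00861496789102
58,0.00938958543738
59,0.0102338529639
60,0.0111540330706
61,0.0121569514608
62,0.0132500475734
63,0.0144414297666
64,0.0157399354643
65,0.01715519671
66,0.0186977116155
67,0.0203789222338
68,0.0222112994333
69,0.0242084354048
70,0.026385144485
71,0.0287575730466
72,0.031343319268
73,0.034161563674
74,0.0372332114117
75,0.0405810473214
76,0.0442299049495
77,0.0482068507583
78,0.0525413848999
79,0.0572656600415
80,0.0624147198677
81,0.068026759027
82,0.0741434064516
83,0.0808100341525
84,0.0880760937789
85,0.095995483441
86,0.104626947514
87,0.114034512394
88,0.124287961426
89,0.135463352553
90,0.147643582485
91,0.160919001622
92,0.175388084243
93,0.191158158978
94,0.20834620494
95,0.227079719459
96,0.247497663825
97,0.269751494078
98,0.294006284474
99,0.320441951974
100,0.349254590829
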