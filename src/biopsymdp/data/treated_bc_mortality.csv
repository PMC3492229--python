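age,value
40,0.12
41,0.121
42,0.122
43,0.123
44,0.124
45,0.125
46,0.126
47,0.127
48,0.128
49,0.129
50,0.13
51,0.131
52,0.132
53,0.133
54,0.134
55,0.135
56,0.136
57,0.137
58,0.138
59,0.139
60,0.14
61,0.141
62,0.142
63,0.143
64,0.144
65,0.145
66,0.146
67,0.147
68,0.148
69,0.149
70,0.15
71,0.151
72,0.152
73,0.153
74,0.154
75,0.155
76,0.156
77,0.157
78,0.158
79,0.159
80,0.16
81,0.161
82,0.162
83,0.163
84,0.164
85,0.165
86,0.166
87,0.167
88,0.168
89,0.169
90,0.17
91,0.171
92,0.172
93,0.173
94,0.174
95,0.175
96,0.176
97,0.177
98,0.178
99,0.179
100,0.18
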