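subject,lead_s
1,30
2,20
3,26
4,25
5,19
6,22
7,32
8,27
9,23
10,29
11,19
12,26
13,28
14,20
15,21
16,23
17,28
18,34
19,27
20,28
21,29
22,29
23,32
24,22
25,28
26,27
27,32
28,19
29,22
30,27
31,29
32,21
33,35
34,32
35,29
36,23
37,26
38,30
39,27
40,22
41,27
42,29
43,24
44,30
45,31
46,26
47,25
48,20
49,23
50,27
51,20
52,31
53,32
54,25
55,25
56,29
57,19
58,20
59,32
60,27
61,20
62,28
63,22
64,26
65,29
66,20
67,30
68,19
69,23
70,27
71,34
72,24
73,20
74,22
75,26
76,30
77,31
78,26
79,24
80,27
81,24
82,27
83,20
84,32
85,21
86,22
87,29
88,27
89,27
90,26
91,34
92,19
93,24
94,29
95,25
96,24
97,22
98,20
99,19
100,29
101,20
102,19
103,27
104,26
105,20
106,31
107,32
108,30
109,27
110,24
111,30
112,33
113,19
114,19
115,25
116,29
117,20
118,31
119,25
120,27
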