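age,qx
0,0.011000
1,0.000626
2,0.000626
3,0.000626
4,0.000626
5,0.000320
6,0.000320
7,0.000320
8,0.000320
9,0.000320
10,0.000400
11,0.000400
12,0.000400
13,0.000400
14,0.000400
15,0.001163
16,0.001163
17,0.001163
18,0.001163
19,0.001163
20,0.001565
21,0.001565
22,0.001565
23,0.001565
24,0.001565
25,0.001666
26,0.001666
27,0.001666
28,0.001666
29,0.001666
30,0.001887
31,0.001887
32,0.001887
33,0.001887
34,0.001887
35,0.002290
36,0.002290
37,0.002290
38,0.002290
39,0.002290
40,0.002978
41,0.002978
42,0.002978
43,0.002978
44,0.002978
45,0.004134
46,0.004134
47,0.004134
48,0.004134
49,0.004134
50,0.005868
51,0.005868
52,0.005868
53,0.005868
54,0.005868
55,0.008441
56,0.008441
57,0.008441
58,0.008441
59,0.008441
60,0.012614
61,0.012614
62,0.012614
63,0.012614
64,0.012614
65,0.019117
66,0.019117
67,0.019117
68,0.019117
69,0.019117
70,0.029714
71,0.029714
72,0.029714
73,0.029714
74,0.029714
75,0.046776
76,0.046776
77,0.046776
78,0.046776
79,0.046776
80,0.073689
81,0.073689
82,0.073689
83,0.073689
84,0.073689
85,0.111088
86,0.111088
87,0.111088
88,0.111088
89,0.111088
90,0.157291
91,0.157291
92,0.157291
93,0.157291
94,0.157291
95,0.213997
96,0.213997
97,0.213997
98,0.213997
99,0.213997
100,1.000000
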