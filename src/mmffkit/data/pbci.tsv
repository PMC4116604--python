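# partial bond charge increments (e) and formal-charge adjustment factors
# columns: type pbci fcadj
1 0.000 0.000
2 -0.135 0.000
3 -0.095 0.000
4 -0.200 0.000
5 -0.023 0.000
6 -0.243 0.000
7 -0.687 0.000
8 -0.253 0.000
9 -0.306 0.000
10 -0.244 0.000
11 -0.317 0.000
12 -0.304 0.000
13 -0.238 0.000
14 -0.208 0.000
15 -0.236 0.000
16 -0.475 0.000
17 -0.191 0.000
18 -0.118 0.000
19 0.094 0.000
20 -0.019 0.000
21 0.157 0.000
22 -0.095 0.000
23 0.193 0.000
24 0.257 0.000
25 0.012 0.000
26 -0.142 0.000
27 0.094 0.000
28 0.058 0.000
29 0.207 0.000
30 -0.166 0.000
31 0.161 0.000
32 -0.732 0.500
33 0.257 0.000
34 -0.491 0.000
35 -0.456 0.500
36 -0.031 0.000
37 -0.127 0.000
38 -0.437 0.000
39 -0.104 0.000
40 -0.264 0.000
41 0.052 0.000
42 -0.757 0.000
43 -0.326 0.000
44 -0.237 0.000
45 -0.260 0.000
46 -0.429 0.000
47 -0.418 0.000
48 -0.525 0.000
49 -0.283 0.000
50 0.284 0.000
51 -1.046 0.000
52 -0.546 0.000
53 -0.048 0.000
54 -0.424 0.000
55 -0.476 0.000
56 -0.438 0.000
57 -0.105 0.000
58 -0.488 0.000
59 -0.337 0.000
60 -0.635 0.000
61 -0.265 0.000
62 -0.125 0.250
63 -0.180 0.000
64 -0.181 0.000
65 -0.475 0.000
66 -0.467 0.000
67 -0.099 0.000
68 -0.135 0.000
69 -0.099 0.000
70 -0.269 0.000
71 -0.071 0.000
72 -0.580 0.500
73 -0.200 0.000
74 -0.301 0.000
75 -0.255 0.000
76 -0.568 0.250
77 -0.282 0.000
78 -0.168 0.000
79 -0.471 0.000
80 -0.144 0.000
81 -0.514 0.000
82 -0.099 0.000
83 0.000 0.000
84 0.000 0.000
85 0.000 0.000
86 0.000 0.000
87 0.000 0.000
88 0.000 0.000
89 0.000 0.000
90 0.000 0.000
91 0.000 0.000
92 1.000 0.000
93 1.000 0.000
94 1.000 0.000
95 2.000 0.000
96 2.000 0.000
97 1.000 0.000
98 2.000 0.000
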