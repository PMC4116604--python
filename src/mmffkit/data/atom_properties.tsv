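# per-numeric-type properties: atomic species, coordination, valence, lone-pair flag, multiple-bond capacity, aromatic flag, linearity flag, stretch-bend eligibility
# columns: type species crd val pilp mltb arom lin sbmb
1 6 4 4 0 0 0 0 0
2 6 3 4 0 2 0 0 1
3 6 3 4 0 2 0 0 1
4 6 2 4 0 3 0 1 1
5 1 1 1 0 0 0 0 0
6 8 2 2 1 0 0 0 0
7 8 1 2 0 2 0 0 0
8 7 3 3 1 0 0 0 0
9 7 2 3 0 2 0 0 1
10 7 3 3 1 1 0 0 0
11 9 1 1 1 0 0 0 0
12 17 1 1 1 0 0 0 0
13 35 1 1 1 0 0 0 0
14 53 1 1 1 0 0 0 0
15 16 2 2 1 0 0 0 0
16 16 1 2 0 2 0 0 0
17 16 3 4 0 2 0 0 0
18 16 4 4 0 0 0 0 0
19 14 4 4 0 0 0 0 0
20 6 4 4 0 0 0 0 0
21 1 1 1 0 0 0 0 0
22 6 4 4 0 0 0 0 0
23 1 1 1 0 0 0 0 0
24 1 1 1 0 0 0 0 0
25 15 4 4 0 0 0 0 0
26 15 3 3 1 0 0 0 0
27 1 1 1 0 0 0 0 0
28 1 1 1 0 0 0 0 0
29 1 1 1 0 0 0 0 0
30 6 3 4 0 2 0 0 1
31 1 1 1 0 0 0 0 0
32 8 1 12 1 1 0 0 0
33 1 1 1 0 0 0 0 0
34 7 4 4 0 0 0 0 0
35 8 1 1 1 1 0 0 0
36 1 1 1 0 0 0 0 0
37 6 3 4 0 2 1 0 1
38 7 2 3 0 2 1 0 0
39 7 3 3 1 1 1 0 1
40 7 3 3 1 0 0 0 0
41 6 3 4 0 1 0 0 0
42 7 1 3 0 3 0 0 0
43 7 3 3 1 0 0 0 0
44 16 2 2 1 1 1 0 0
45 7 3 4 0 2 0 0 0
46 7 2 3 0 2 0 0 0
47 7 1 2 0 2 0 0 0
48 7 2 2 0 0 0 0 0
49 8 3 3 0 0 0 0 0
50 1 1 1 0 0 0 0 0
51 8 2 3 0 2 0 0 0
52 1 1 1 0 0 0 0 0
53 7 2 4 0 2 0 1 0
54 7 3 4 0 2 0 0 1
55 7 3 34 0 1 0 0 0
56 7 3 34 0 1 0 0 0
57 6 3 4 0 2 0 0 1
58 7 3 4 0 1 1 0 1
59 8 2 2 1 1 1 0 0
60 6 1 3 0 3 0 0 0
61 7 2 4 0 3 0 1 0
62 7 2 2 1 0 0 0 0
63 6 3 4 0 2 1 0 1
64 6 3 4 0 2 1 0 1
65 7 2 3 0 2 1 0 0
66 7 2 3 0 2 1 0 0
67 7 3 4 0 2 0 0 1
68 7 4 4 0 0 0 0 0
69 7 3 4 0 1 1 0 0
70 8 2 2 1 0 0 0 0
71 1 1 1 0 0 0 0 0
72 16 1 1 1 1 0 0 0
73 16 3 3 0 0 0 0 0
74 16 2 4 0 2 0 0 0
75 15 2 3 0 2 0 0 1
76 7 2 2 1 0 0 0 0
77 17 4 4 0 0 0 0 0
78 6 3 4 0 2 1 0 1
79 7 2 3 0 2 1 0 0
80 6 3 4 0 2 0 0 1
81 7 3 4 0 1 1 0 1
82 7 3 4 0 1 1 0 0
87 26 0 0 0 0 0 0 0
88 26 0 0 0 0 0 0 0
89 9 0 0 0 0 0 0 0
90 17 0 0 0 0 0 0 0
91 35 0 0 0 0 0 0 0
92 3 0 0 0 0 0 0 0
93 11 0 0 0 0 0 0 0
94 19 0 0 0 0 0 0 0
95 30 0 0 0 0 0 0 0
96 20 0 0 0 0 0 0 0
97 29 0 0 0 0 0 0 0
98 29 0 0 0 0 0 0 0
99 12 0 0 0 0 0 0 0
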