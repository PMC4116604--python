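# step-down equivalence table: increasingly generic surrogate numeric types (0 = wildcard)
# columns: type level2 level3 level4 level5
1 1 1 1 0
2 2 2 1 0
3 3 3 1 0
4 4 4 1 0
5 5 5 5 0
6 6 6 6 0
7 7 7 6 0
8 8 8 8 0
9 9 9 8 0
10 10 10 8 0
11 11 11 11 0
12 12 12 12 0
13 13 13 13 0
14 14 14 14 0
15 15 15 15 0
16 16 16 15 0
17 17 17 15 0
18 18 18 15 0
19 19 19 19 0
20 20 1 1 0
21 21 21 5 0
22 22 22 1 0
23 23 23 5 0
24 24 24 5 0
25 25 25 25 0
26 26 26 25 0
27 27 28 5 0
28 28 28 5 0
29 29 29 5 0
30 30 2 1 0
31 31 31 31 0
32 32 7 6 0
33 33 21 5 0
34 34 8 8 0
35 35 6 6 0
36 36 36 5 0
37 37 2 1 0
38 38 9 8 0
39 39 10 8 0
40 40 10 8 0
41 41 3 1 0
42 42 42 8 0
43 43 10 8 0
44 44 16 15 0
45 45 10 8 0
46 46 9 8 0
47 47 42 8 0
48 48 9 8 0
49 49 6 6 0
50 50 21 5 0
51 51 7 6 0
52 52 21 5 0
53 53 42 8 0
54 54 9 8 0
55 55 10 8 0
56 56 10 8 0
57 57 2 1 0
58 58 10 8 0
59 59 6 6 0
60 60 4 1 0
61 61 42 8 0
62 62 10 8 0
63 63 2 1 0
64 64 2 1 0
65 65 9 8 0
66 66 9 8 0
67 67 9 8 0
68 68 8 8 0
69 69 9 8 0
70 70 70 70 70
71 71 5 5 0
72 72 16 15 0
73 73 18 15 0
74 74 17 15 0
75 75 26 25 0
76 76 9 8 0
77 77 12 12 0
78 78 2 1 0
79 79 9 8 0
80 80 2 1 0
81 81 10 8 0
82 82 9 8 0
87 87 87 87 87
88 88 88 88 88
89 89 89 89 89
90 90 90 90 90
91 91 91 91 91
92 92 92 92 92
93 93 93 93 93
94 94 94 94 94
95 95 95 95 95
96 96 96 96 96
97 97 97 97 97
98 98 98 98 98
99 99 99 99 99
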