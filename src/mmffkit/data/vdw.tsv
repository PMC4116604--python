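# MMFF buffered 14-7 vdW parameters: polarizability alpha (A^3), Slater-Kirkwood N, scale A, scale G, donor/acceptor class (-/D/A)
# columns: type alpha N A G DA
1 1.050 2.490 3.890 1.282 -
2 1.350 2.490 3.890 1.282 -
3 1.100 2.490 3.890 1.282 -
4 1.300 2.490 3.890 1.282 -
5 0.250 0.800 4.200 1.209 -
6 0.70 3.150 3.890 1.282 A
7 0.65 3.150 3.890 1.282 A
8 1.15 2.820 3.890 1.282 A
9 0.90 2.820 3.890 1.282 A
10 1.000 2.820 3.890 1.282 A
11 0.35 3.480 3.890 1.282 A
12 2.300 5.100 3.320 1.345 A
13 3.400 6.000 3.190 1.359 A
14 5.500 6.950 3.080 1.404 A
15 3.00 4.800 3.320 1.345 A
16 3.900 4.800 3.320 1.345 A
17 2.700 4.800 3.320 1.345 -
18 2.100 4.800 3.320 1.345 -
19 4.500 4.200 3.320 1.345 -
20 1.050 2.490 3.890 1.282 -
21 0.150 0.800 4.200 1.209 D
22 1.100 2.490 3.890 1.282 -
23 0.150 0.800 4.200 1.209 D
24 0.150 0.800 4.200 1.209 D
25 1.600 4.500 3.320 1.345 -
26 3.600 4.500 3.320 1.345 A
27 0.150 0.800 4.200 1.209 D
28 0.150 0.800 4.200 1.209 D
29 0.150 0.800 4.200 1.209 D
30 1.350 2.490 3.890 1.282 -
31 0.150 0.800 4.200 1.209 D
32 0.75 3.150 3.890 1.282 A
33 0.150 0.800 4.200 1.209 D
34 1.00 2.820 3.890 1.282 -
35 1.50 3.150 3.890 1.282 A
36 0.150 0.800 4.200 1.209 D
37 1.350 2.490 3.890 1.282 -
38 0.85 2.820 3.890 1.282 A
39 1.10 2.820 3.890 1.282 -
40 1.00 2.820 3.890 1.282 A
41 1.100 2.490 3.890 1.282 -
42 1.000 2.820 3.890 1.282 A
43 1.000 2.820 3.890 1.282 A
44 3.00 4.800 3.320 1.345 A
45 1.150 2.820 3.890 1.282 -
46 1.300 2.820 3.890 1.282 -
47 1.000 2.820 3.890 1.282 A
48 1.200 2.820 3.890 1.282 A
49 1.00 3.150 3.890 1.282 -
50 0.150 0.800 4.200 1.209 D
51 0.400 3.150 3.890 1.282 -
52 0.150 0.800 4.200 1.209 D
53 1.000 2.820 3.890 1.282 -
54 1.30 2.820 3.890 1.282 -
55 0.80 2.820 3.890 1.282 -
56 0.80 2.820 3.890 1.282 -
57 1.000 2.490 3.890 1.282 -
58 0.80 2.820 3.890 1.282 -
59 0.65 3.150 3.890 1.282 A
60 1.800 2.490 3.890 1.282 A
61 0.800 2.820 3.890 1.282 A
62 1.300 2.820 3.890 1.282 A
63 1.350 2.490 3.890 1.282 -
64 1.350 2.490 3.890 1.282 -
65 1.000 2.820 3.890 1.282 A
66 0.75 2.820 3.890 1.282 A
67 0.950 2.82 3.890 1.282 A
68 0.90 2.82 3.890 1.282 A
69 0.950 2.82 3.890 1.282 A
70 0.87 3.150 3.890 1.282 A
71 0.150 0.800 4.200 1.209 D
72 4.000 4.800 3.320 1.345 A
73 3.000 4.800 3.320 1.345 -
74 3.000 4.800 3.320 1.345 -
75 4.000 4.500 3.320 1.345 A
76 1.200 2.820 3.890 1.282 A
77 1.500 5.100 3.320 1.345 A
78 1.350 2.490 3.890 1.282 -
79 1.000 2.820 3.890 1.282 A
80 1.000 2.490 3.890 1.282 -
81 0.80 2.820 3.890 1.282 -
82 0.950 2.82 3.890 1.282 A
87 0.45 6. 4. 1.4 -
88 0.55 6. 4. 1.4 -
89 1.4 3.48 3.890 1.282 A
90 4.5 5.100 3.320 1.345 A
91 6.0 6.000 3.190 1.359 A
92 0.15 2. 4. 1.3 -
93 0.4 3.5 4. 1.3 -
94 1.0 5. 4. 1.3 -
95 0.43 6. 4. 1.4 -
96 0.9 5. 4. 1.4 -
97 0.35 6. 4. 1.4 -
98 0.40 6. 4. 1.4 -
99 0.35 3.5 4. 1.3 -
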