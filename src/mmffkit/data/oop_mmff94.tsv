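# MMFF out-of-plane parameters (Wilson angle), j = trigonal center; koop in md-A/rad^2
# columns: i j k l koop
1 2 1 2 0.030
1 2 2 2 0.027
1 2 2 3 0.026
1 2 2 5 0.013
1 2 2 37 0.032
2 2 2 5 0.013
2 2 3 5 0.012
2 2 5 5 0.006
2 2 5 6 0.027
2 2 5 37 0.017
2 2 5 40 0.012
2 2 5 41 0.008
0 2 0 0 0.020
1 3 1 7 0.146
1 3 2 7 0.138
1 3 3 7 0.134
1 3 5 7 0.122
1 3 6 7 0.141
1 3 7 10 0.129
1 3 7 37 0.138
2 3 5 7 0.113
2 3 5 9 0.081
2 3 6 7 0.127
2 3 7 10 0.116
3 3 5 7 0.113
3 3 6 7 0.127
5 3 5 7 0.103
5 3 5 9 0.074
5 3 5 54 0.078
5 3 6 7 0.119
5 3 7 10 0.102
5 3 9 40 0.067
6 3 7 37 0.127
7 3 10 10 0.113
7 3 20 20 0.151
9 3 40 40 0.057
0 3 0 0 0.130
0 8 0 0 0.000
1 10 1 3 -0.02
1 10 3 6 -0.033
1 10 3 28 -0.02
3 10 3 28 -0.030
3 10 28 28 -0.019
0 10 0 0 -0.020
0 17 0 0 0.000
0 26 0 0 0.000
5 30 20 30 0.008
0 30 0 0 0.010
1 37 37 37 0.040
2 37 37 37 0.031
3 37 37 37 0.027
5 37 37 37 0.015
5 37 37 38 0.046
5 37 37 63 0.008
5 37 37 64 0.012
5 37 37 69 0.016
5 37 38 38 0.084
6 37 37 37 0.048
15 37 37 37 0.025
37 37 37 40 0.046
0 37 0 0 0.035
1 39 63 63 0.012
23 39 63 63 -0.014
23 39 63 65 0.021
23 39 65 65 0.062
0 39 0 0 0.020
1 40 28 37 -0.006
2 40 28 28 -0.007
3 40 28 28 -0.007
28 40 28 37 0.004
0 40 0 0 -0.005
1 41 32 32 0.178
2 41 32 32 0.161
5 41 32 32 0.158
0 41 0 0 0.180
0 43 0 0 0.000
0 45 0 0 0.150
50 49 50 50 0.000
0 49 0 0 0.000
1 54 3 36 0.016
3 54 36 36 0.018
0 54 0 0 0.020
1 55 36 57 0.020
36 55 36 57 0.020
0 55 0 0 0.020
1 56 36 57 0.020
36 56 36 57 0.020
0 56 0 0 0.020
5 57 55 55 0.038
56 57 56 56 0.158
0 57 0 0 0.080
0 58 0 0 0.025
5 63 39 64 0.019
5 63 39 66 0.068
5 63 44 64 0.014
5 63 44 66 0.055
5 63 59 64 0.033
5 63 59 66 0.085
37 63 39 64 0.010
0 63 0 0 0.050
5 64 63 64 0.006
5 64 63 66 0.043
5 64 64 65 0.052
5 64 65 66 0.094
37 64 63 64 -0.011
0 64 0 0 0.040
0 67 0 0 0.070
32 69 37 37 0.067
0 69 0 0 0.070
0 73 0 0 0.000
5 78 78 81 0.046
0 78 0 0 0.045
5 80 81 81 0.057
0 80 0 0 0.080
36 81 78 80 0.016
0 81 0 0 0.025
0 82 0 0 0.000
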