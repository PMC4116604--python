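# MMFF stretch-bend coupling constants (md/rad)
# columns: sbt i j k kba_ijk kba_kji
0 1 1 1 0.206 0.206
0 1 1 2 0.136 0.197
0 1 1 3 0.211 0.092
0 1 1 5 0.227 0.070
0 1 1 6 0.173 0.417
0 1 1 8 0.136 0.282
0 1 1 10 0.187 0.338
0 1 1 11 0.209 0.633
0 1 1 12 0.176 0.386
0 1 1 15 0.139 0.217
0 1 1 34 0.236 0.436
0 1 1 37 0.152 0.260
0 1 1 39 0.144 0.595
0 1 1 41 0.122 0.051
0 1 1 56 0.262 0.451
0 1 1 68 0.186 0.125
0 2 1 2 0.282 0.282
0 2 1 3 0.206 0.022
0 2 1 5 0.234 0.088
0 2 1 6 0.183 0.387
0 2 1 8 0.214 0.363
0 3 1 5 0.157 0.115
0 3 1 6 -0.036 0.456
0 3 1 10 0.038 0.195
0 5 1 5 0.115 0.115
0 5 1 6 0.013 0.436
0 5 1 8 0.027 0.358
0 5 1 9 0.040 0.418
0 5 1 10 0.043 0.261
0 5 1 11 0.003 0.452
0 5 1 12 -0.018 0.380
0 5 1 15 0.018 0.255
0 5 1 18 0.121 0.218
0 5 1 20 0.069 0.327
0 5 1 22 0.055 0.267
0 5 1 34 -0.003 0.342
0 5 1 37 0.074 0.287
0 5 1 39 0.092 0.607
0 5 1 40 0.023 0.335
0 5 1 41 0.093 0.118
0 5 1 54 0.016 0.343
0 5 1 55 0.030 0.397
0 5 1 56 0.031 0.384
0 5 1 68 0.041 0.216
0 6 1 6 0.320 0.320
0 6 1 37 0.310 0.160
0 11 1 11 0.586 0.586
0 12 1 12 0.508 0.508
0 1 2 1 0.250 0.250
0 1 2 2 0.203 0.207
2 1 2 2 0.222 0.269
2 1 2 3 0.244 0.292
0 1 2 5 0.215 0.128
2 1 2 37 0.246 0.260
1 2 2 2 0.250 0.219
2 2 2 3 0.155 0.112
0 2 2 5 0.207 0.157
1 2 2 5 0.267 0.159
0 2 2 6 0.118 0.576
2 2 2 37 0.143 0.172
0 2 2 40 0.289 0.390
0 2 2 41 0.191 -0.047
1 3 2 5 0.264 0.156
0 5 2 5 0.140 0.140
0 5 2 6 0.213 0.502
2 5 2 37 0.153 0.288
0 5 2 40 0.070 0.463
0 5 2 41 0.191 0.005
0 1 3 1 0.358 0.358
2 1 3 2 0.246 0.409
2 1 3 3 0.303 0.145
0 1 3 5 0.321 0.183
0 1 3 6 0.338 0.732
0 1 3 7 0.154 0.856
0 1 3 10 0.223 0.732
2 1 3 37 0.217 0.207
1 2 3 5 0.407 0.159
1 2 3 6 0.429 0.473
1 2 3 7 0.214 0.794
1 2 3 9 0.227 0.610
1 2 3 10 0.298 0.600
1 3 3 5 0.251 0.133
1 3 3 6 0.066 0.668
1 3 3 7 -0.093 0.866
0 5 3 5 0.126 0.126
0 5 3 6 0.174 0.734
0 5 3 7 0.032 0.805
0 5 3 9 0.037 0.669
0 5 3 10 0.169 0.619
0 5 3 40 0.087 0.685
0 5 3 54 0.098 0.210
0 6 3 7 0.494 0.578
4 6 3 20 1.179 0.752
2 6 3 37 0.350 0.175
0 7 3 10 0.771 0.353
0 7 3 20 0.865 -0.181
2 7 3 37 0.707 0.007
0 9 3 40 0.680 0.260
0 10 3 10 1.050 1.050
4 20 3 20 0.536 0.536
0 40 3 40 0.482 0.482
0 1 6 1 0.309 0.309
0 1 6 2 0.157 0.375
0 1 6 3 -0.153 0.252
0 1 6 21 0.256 0.143
0 1 6 37 0.163 0.375
0 2 6 3 -0.228 0.052
0 2 6 29 0.259 0.163
4 3 6 20 0.456 0.379
0 3 6 24 0.215 0.064
0 3 6 37 -0.225 -0.320
0 8 6 21 0.304 0.055
0 10 6 21 0.419 0.158
0 18 6 33 0.309 0.120
4 20 6 20 0.739 0.739
0 29 6 37 0.130 0.241
0 31 6 31 0.227 0.227
0 1 8 1 0.312 0.312
0 1 8 6 0.212 0.354
0 1 8 23 0.309 0.135
0 6 8 23 0.418 0.020
4 20 8 20 0.653 0.653
0 20 8 23 0.128 0.122
0 23 8 23 0.190 0.190
0 1 9 3 0.326 0.580
0 3 9 27 0.464 0.222
0 1 10 1 0.063 0.063
0 1 10 3 -0.021 0.340
0 1 10 6 -0.024 0.374
0 1 10 28 0.155 -0.051
0 3 10 3 -0.219 -0.219
0 3 10 6 0.497 0.513
0 3 10 28 0.137 0.066
0 28 10 28 0.081 0.081
0 1 15 1 0.125 0.125
0 1 15 15 0.012 0.238
0 1 15 37 0.048 0.229
0 1 15 71 0.080 -0.012
0 15 15 71 0.172 -0.068
0 37 15 71 0.187 -0.027
0 71 15 71 0.045 0.045
0 1 18 1 0.023 0.023
0 1 18 6 0.003 0.213
0 1 18 32 -0.091 0.390
0 1 18 43 -0.008 0.607
0 6 18 6 0.088 0.088
0 6 18 32 0.123 0.369
0 32 18 32 0.404 0.404
0 32 18 43 0.384 0.281
0 43 18 43 0.428 0.428
0 1 20 5 0.290 0.098
0 1 20 20 0.179 0.004
0 3 20 5 -0.049 0.171
4 3 20 20 0.607 0.437
0 5 20 5 0.182 0.182
0 5 20 6 0.051 0.312
0 5 20 8 0.072 0.226
0 5 20 12 0.014 0.597
0 5 20 20 0.101 0.079
0 5 20 30 0.108 0.123
4 6 20 20 0.823 0.396
4 8 20 20 0.701 0.369
0 12 20 20 0.310 0.000
4 20 20 20 0.283 0.283
4 20 20 30 0.340 0.529
0 1 22 5 0.067 0.174
0 1 22 22 0.199 0.039
0 5 22 5 0.254 0.254
0 5 22 22 0.181 0.108
5 22 22 22 0.000 0.000
0 5 26 5 -0.121 -0.121
0 5 30 20 0.251 0.007
0 5 30 30 0.267 0.054
4 20 30 30 0.413 0.705
0 1 34 1 0.202 0.202
0 1 34 36 0.160 -0.009
0 36 34 36 0.087 0.087
0 1 37 37 0.485 0.311
1 2 37 37 0.321 0.235
1 3 37 37 0.179 0.217
0 5 37 37 0.279 0.250
0 5 37 38 0.267 0.389
0 5 37 63 0.216 0.434
0 5 37 64 0.167 0.364
0 5 37 69 0.273 0.391
0 6 37 37 0.830 0.339
0 15 37 37 0.650 0.259
0 37 37 37 -0.411 -0.411
0 37 37 38 -0.424 -0.466
0 37 37 40 0.429 0.901
0 37 37 63 -0.173 -0.215
0 37 37 64 -0.229 -0.229
0 37 37 69 -0.244 -0.555
0 38 37 38 -0.516 -0.516
0 37 38 37 -0.342 -0.342
0 37 38 38 -0.164 -1.130
0 1 39 63 0.313 0.500
0 23 39 63 -0.131 0.422
0 23 39 65 -0.122 0.281
0 63 39 63 0.469 0.469
0 63 39 65 0.741 0.506
0 65 39 65 0.706 0.706
0 1 40 28 0.238 0.091
0 1 40 37 0.153 0.590
0 2 40 28 0.342 0.156
0 3 40 28 0.228 0.104
0 28 40 28 0.094 0.094
0 28 40 37 0.186 0.423
0 1 41 32 0.503 0.943
0 2 41 32 0.594 0.969
0 5 41 32 0.276 0.852
0 32 41 32 0.652 0.652
0 18 43 23 0.377 0.057
0 23 43 23 0.082 0.082
0 63 44 63 0.591 0.591
0 63 44 65 0.857 0.978
0 50 49 50 0.072 0.072
0 1 54 3 0.192 -0.051
0 1 54 36 0.240 0.079
0 3 54 36 0.005 0.127
0 36 54 36 0.148 0.148
0 1 55 36 0.189 0.033
0 1 55 57 0.166 0.211
0 36 55 36 0.106 0.106
0 36 55 57 0.093 0.080
0 1 56 36 0.211 -0.040
0 1 56 57 0.026 0.386
0 36 56 36 0.101 0.101
0 36 56 57 0.108 0.068
0 5 57 55 0.043 0.420
0 55 57 55 0.125 0.125
0 56 57 56 0.431 0.431
0 58 57 58 0.732 0.732
0 63 59 63 0.497 0.497
0 63 59 65 0.723 0.874
0 5 63 39 0.009 0.654
0 5 63 44 -0.015 0.446
0 5 63 59 0.067 0.588
0 5 63 64 0.055 0.370
0 5 63 66 0.110 0.464
0 37 63 39 0.178 0.523
0 37 63 64 -0.045 0.497
0 39 63 64 0.422 0.409
0 39 63 66 0.436 0.525
0 44 63 64 0.581 0.426
0 44 63 66 0.542 0.365
0 59 63 64 0.852 0.332
0 59 63 66 0.775 0.300
0 5 64 63 0.086 0.345
0 5 64 64 0.085 0.369
0 5 64 65 0.051 0.436
0 5 64 66 0.113 0.452
0 37 64 63 0.059 0.299
0 37 64 64 0.277 0.377
0 63 64 64 0.206 0.030
0 63 64 66 0.171 0.078
0 64 64 65 0.079 0.403
0 65 64 66 0.406 0.066
0 39 65 64 0.528 0.644
0 39 65 66 0.397 0.258
0 44 65 64 0.816 0.543
0 59 65 64 1.177 0.594
0 63 66 64 0.213 -0.173
0 63 66 66 0.234 0.077
0 64 66 65 -0.149 0.383
0 65 66 66 0.199 0.101
0 1 68 1 0.217 0.217
0 1 68 23 0.285 0.050
0 1 68 32 -0.047 0.503
0 23 68 23 0.145 0.145
0 23 68 32 -0.182 0.504
0 32 69 37 1.018 0.418
0 37 69 37 -0.169 -0.169
0 31 70 31 0.210 0.210
0 5 78 78 0.279 0.250
0 5 78 81 0.083 0.250
0 78 78 81 -0.398 0.314
0 5 80 81 -0.101 0.691
0 81 80 81 0.732 0.732
0 36 81 78 0.021 0.368
0 36 81 80 0.018 0.422
0 78 81 80 0.366 0.419
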