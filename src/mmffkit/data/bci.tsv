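# MMFF bond charge increments (e); for key (bt,i,j) with i<j the atom of type j receives +bci, the atom of type i receives -bci
# columns: bt i j bci
0 1 1 0.0000
0 1 2 -0.1382
0 1 3 -0.0610
0 1 4 -0.2000
0 1 5 0.0000
0 1 6 -0.2800
0 1 8 -0.2700
0 1 9 -0.2460
0 1 10 -0.3001
0 1 11 -0.3400
0 1 12 -0.2900
0 1 13 -0.2300
0 1 14 -0.1900
0 1 15 -0.2300
0 1 17 -0.1935
0 1 18 -0.1052
0 1 19 0.0805
0 1 20 0.0000
0 1 22 -0.0950
0 1 25 0.0000
0 1 26 -0.1669
0 1 34 -0.5030
0 1 35 -0.4274
0 1 37 -0.1435
0 1 39 -0.2556
0 1 40 -0.3691
0 1 41 0.1060
0 1 43 -0.3557
0 1 45 -0.2402
0 1 46 -0.3332
0 1 54 -0.3461
0 1 55 -0.4895
0 1 56 -0.3276
0 1 57 -0.1050
0 1 58 -0.4880
0 1 61 -0.2657
0 1 62 -0.2000
0 1 63 -0.1800
0 1 64 -0.1810
0 1 67 -0.0990
0 1 68 -0.2560
0 1 72 -0.5500
0 1 73 -0.0877
0 1 75 -0.2550
0 1 78 -0.1680
0 1 80 -0.1440
0 1 81 -0.5140
0 2 2 0.0000
1 2 2 0.0000
1 2 3 -0.0144
0 2 4 -0.0650
1 2 4 -0.0650
0 2 5 0.1500
0 2 6 -0.0767
1 2 9 -0.1710
0 2 10 -0.1090
0 2 11 -0.1495
0 2 12 -0.1400
0 2 13 -0.1100
0 2 14 -0.0900
0 2 15 -0.1010
0 2 17 -0.0560
0 2 18 0.0170
0 2 19 0.2290
0 2 20 0.1160
0 2 22 0.0400
0 2 25 0.1470
0 2 30 -0.0310
0 2 34 -0.3560
0 2 35 -0.3500
1 2 37 0.0284
1 2 39 0.0310
0 2 40 -0.1000
0 2 41 0.2500
0 2 43 -0.1910
0 2 45 -0.2044
0 2 46 -0.2940
0 2 55 -0.3410
0 2 56 -0.3030
0 2 62 -0.0500
1 2 63 -0.0450
1 2 64 -0.0460
1 2 67 0.0360
0 2 72 -0.4500
1 2 81 -0.3790
1 3 3 0.0000
1 3 4 -0.1050
0 3 5 0.0600
0 3 6 -0.1500
0 3 7 -0.5700
0 3 9 -0.4500
1 3 9 -0.2110
0 3 10 -0.0600
0 3 11 -0.2220
0 3 12 -0.2090
0 3 15 -0.1410
0 3 16 -0.3800
0 3 17 -0.0960
0 3 18 -0.0230
0 3 20 0.0530
0 3 22 0.0000
0 3 25 0.1070
1 3 30 -0.0710
0 3 35 -0.3610
1 3 37 0.0862
1 3 39 -0.0090
0 3 40 -0.0500
0 3 41 0.1470
0 3 43 -0.2363
0 3 45 -0.1650
0 3 48 -0.4300
0 3 51 -0.9500
0 3 53 -0.0134
0 3 54 -0.4000
1 3 54 -0.3290
0 3 55 -0.3810
0 3 56 -0.3430
1 3 57 -0.0100
1 3 58 -0.3930
0 3 62 -0.0300
1 3 63 -0.0850
1 3 64 -0.0860
0 3 67 -0.0040
0 3 74 -0.3190
0 3 75 -0.2474
1 3 78 -0.0730
1 3 80 -0.0490
0 4 5 0.1770
0 4 6 -0.0430
0 4 7 -0.4870
0 4 9 -0.3000
1 4 9 -0.1060
0 4 10 -0.0440
0 4 15 -0.0360
0 4 20 0.1810
0 4 22 0.1050
0 4 30 0.0340
1 4 37 0.0730
0 4 40 -0.0640
0 4 42 -0.5571
0 4 43 -0.1260
1 4 63 0.0200
1 4 64 0.0190
0 5 19 0.2000
0 5 20 0.0000
0 5 22 -0.1000
0 5 30 -0.1500
0 5 37 -0.1500
0 5 41 0.2203
0 5 57 -0.1500
0 5 63 -0.1500
0 5 64 -0.1500
0 5 78 -0.1500
0 5 80 -0.1500
0 6 6 0.0000
0 6 8 -0.1000
0 6 9 -0.0630
0 6 10 0.0355
0 6 15 0.0070
0 6 17 0.0520
0 6 18 0.1837
0 6 19 0.2974
0 6 20 0.2579
0 6 21 0.4000
0 6 22 0.1480
0 6 24 0.5000
0 6 25 0.2712
0 6 26 0.1010
0 6 29 0.4500
0 6 30 0.0770
0 6 33 0.5000
0 6 37 0.0825
0 6 39 0.1390
0 6 40 -0.0210
0 6 41 0.2950
0 6 43 -0.0830
0 6 45 -0.0090
0 6 54 -0.1810
0 6 55 -0.2330
0 6 57 0.1380
0 6 58 -0.2450
0 6 63 0.0630
0 6 64 0.0620
0 7 17 0.5000
0 7 46 0.1618
0 7 74 0.5000
0 8 8 0.0000
0 8 9 -0.0530
0 8 10 0.0090
0 8 12 -0.0510
0 8 15 0.0170
0 8 17 0.0620
0 8 19 0.3470
0 8 20 0.2096
0 8 22 0.1580
0 8 23 0.3600
0 8 25 0.2679
0 8 26 0.1110
0 8 34 -0.2380
0 8 39 0.1490
0 8 40 -0.0110
0 8 43 -0.0730
0 8 45 -0.0070
0 8 46 -0.1760
0 8 55 -0.2230
0 8 56 -0.1850
0 9 9 0.0000
0 9 10 0.0620
0 9 12 0.0020
0 9 15 0.0700
0 9 18 0.1880
0 9 19 0.4000
0 9 20 0.2870
0 9 25 0.3180
0 9 27 0.4000
0 9 34 -0.1850
0 9 35 -0.1500
1 9 37 0.1790
1 9 39 0.2020
0 9 40 0.0420
0 9 41 0.3580
0 9 45 0.0460
0 9 53 0.3179
0 9 54 -0.1180
0 9 55 -0.1700
0 9 56 -0.1320
1 9 57 0.2010
0 9 62 0.1810
1 9 63 0.1260
1 9 64 0.1250
0 9 67 0.2070
1 9 78 0.1380
1 9 81 -0.2080
0 10 10 0.0000
0 10 13 0.0060
0 10 14 0.0360
0 10 15 0.0080
0 10 17 0.0530
0 10 20 0.2250
0 10 22 0.1490
0 10 25 0.2560
0 10 26 0.1020
0 10 28 0.3700
0 10 34 -0.2470
0 10 35 -0.2120
0 10 37 0.1170
0 10 39 0.1400
0 10 40 -0.0200
0 10 41 0.2960
0 10 45 -0.0160
0 10 63 0.0640
0 10 64 0.0630
0 11 20 0.2980
0 11 22 0.2317
0 11 25 0.3290
0 11 26 0.1750
0 11 37 0.1900
0 11 40 0.0530
0 12 15 0.0680
0 12 18 0.1860
0 12 19 0.3701
0 12 20 0.2900
0 12 22 0.2273
0 12 25 0.3160
0 12 26 0.2112
0 12 37 0.1770
0 12 40 0.0400
0 12 57 0.1990
0 12 63 0.1240
0 12 64 0.1230
0 13 20 0.2190
0 13 22 0.1430
0 13 37 0.1110
0 13 64 0.0570
0 14 20 0.1890
0 14 37 0.0810
0 15 15 0.0000
0 15 18 0.1180
0 15 19 0.3300
0 15 20 0.2170
0 15 22 0.1410
0 15 25 0.2480
0 15 26 0.0940
0 15 30 0.0700
0 15 37 0.1015
0 15 40 -0.0280
0 15 43 -0.0900
0 15 57 0.1310
0 15 63 0.0560
0 15 64 0.0550
0 15 71 0.1800
0 16 16 0.0000
0 17 17 0.0000
0 17 20 0.1720
0 17 22 0.0960
0 17 37 0.0640
0 17 43 -0.1350
0 18 18 0.0000
0 18 20 0.0990
0 18 22 0.0230
0 18 32 -0.6500
0 18 37 -0.0090
0 18 39 0.0140
0 18 43 -0.1380
0 18 48 -0.5895
0 18 55 -0.3580
0 18 58 -0.3700
0 18 62 0.2099
0 18 63 -0.0620
0 18 64 -0.0630
0 18 80 -0.0260
0 19 19 0.0000
0 19 20 -0.1130
0 19 37 -0.2210
0 19 40 -0.3580
0 19 63 -0.2740
0 19 75 -0.3490
0 20 20 0.0000
0 20 22 -0.0760
0 20 25 0.0310
0 20 26 -0.1230
0 20 30 -0.1380
0 20 34 -0.4720
0 20 37 -0.1080
0 20 40 -0.2450
0 20 41 0.0710
0 20 43 -0.3070
0 20 45 -0.2410
0 22 22 0.0000
0 22 30 -0.0710
0 22 34 -0.3960
0 22 37 -0.0320
0 22 40 -0.1690
0 22 41 0.1470
0 22 43 -0.2310
0 22 45 -0.1650
0 23 39 -0.2700
0 23 62 -0.4000
0 23 67 -0.2920
0 23 68 -0.3600
0 25 25 0.0000
0 25 32 -0.7000
0 25 37 -0.1390
0 25 39 -0.1160
0 25 40 -0.2760
0 25 43 -0.3380
0 25 57 -0.1170
0 25 63 -0.1920
0 25 71 -0.0362
0 25 72 -0.6773
0 26 26 0.0000
0 26 34 -0.3490
0 26 37 0.0150
0 26 40 -0.1220
0 26 71 0.0960
0 28 40 -0.4000
0 28 43 -0.4200
0 28 48 -0.4000
0 30 30 0.0000
0 30 40 -0.0980
1 30 67 0.0670
0 31 70 -0.4300
0 32 41 0.6500
0 32 45 0.5200
0 32 67 0.6330
0 32 68 0.7500
0 32 69 0.7500
0 32 73 0.3500
0 32 77 0.4500
0 32 82 0.6330
0 34 36 0.4500
0 34 37 0.3640
0 34 43 0.1650
0 35 37 0.3290
0 35 63 0.2760
0 36 54 -0.4000
0 36 55 -0.4500
0 36 56 -0.4500
0 36 58 -0.4570
4 36 58 -0.4500
0 36 81 -0.4500
0 37 37 0.0000
1 37 37 0.0000
0 37 38 -0.3100
0 37 39 0.0230
1 37 39 0.0230
0 37 40 -0.1000
0 37 41 0.1790
0 37 43 -0.1990
0 37 45 -0.1330
0 37 46 -0.3020
0 37 55 -0.3490
0 37 56 -0.3110
1 37 57 0.0220
0 37 58 -0.3610
1 37 58 -0.3610
4 37 58 -0.3500
0 37 61 -0.1380
0 37 62 0.0020
0 37 63 0.0000
1 37 63 -0.0530
0 37 64 0.0000
1 37 64 -0.0540
1 37 67 0.0280
0 37 69 -0.0895
0 37 78 -0.0410
0 37 81 -0.3870
1 37 81 -0.3870
0 38 38 0.0000
0 38 63 0.2570
0 38 64 0.2560
0 38 69 0.3380
0 38 78 0.2690
1 39 39 0.0000
0 39 40 -0.1600
0 39 45 -0.1560
0 39 63 -0.1516
1 39 63 -0.0760
0 39 64 -0.0770
1 39 64 -0.0770
0 39 65 -0.4180
0 39 78 -0.0640
0 40 40 0.0000
0 40 45 0.0040
0 40 46 -0.1650
0 40 54 -0.1600
0 40 63 0.0840
0 40 64 0.0830
0 40 78 0.0960
0 41 41 0.0000
0 41 55 -0.5280
0 41 62 -0.1770
0 41 72 -0.5000
0 41 80 -0.1960
0 42 61 0.4920
0 43 43 0.0000
0 43 45 0.0660
0 43 64 0.1450
0 44 63 0.0400
0 44 65 -0.2207
0 44 78 0.0690
0 44 80 0.0930
0 45 63 0.0800
0 45 64 0.0790
0 45 78 0.0920
0 47 53 0.3700
0 49 50 0.5673
0 51 52 0.5000
0 55 57 0.3544
0 55 62 0.3510
0 55 64 0.2950
0 55 80 0.3320
0 56 57 0.4000
0 56 63 0.2580
0 56 80 0.2700
4 57 58 -0.4000
1 57 63 -0.0750
1 57 64 -0.0760
0 58 63 0.3080
0 58 64 0.3070
0 59 63 0.1400
0 59 65 -0.1209
0 59 78 0.1690
0 59 80 0.1930
0 59 82 0.2380
0 60 61 0.3700
0 62 63 -0.0550
0 62 64 -0.0560
0 63 63 0.0000
1 63 63 0.0000
0 63 64 0.0000
0 63 66 -0.3381
0 63 72 -0.4000
0 63 78 0.0120
0 63 81 -0.3340
0 64 64 0.0000
0 64 65 -0.2888
0 64 66 -0.2272
0 64 78 0.0130
0 64 81 -0.3330
0 64 82 0.0820
0 65 66 0.0000
0 65 78 0.3070
0 65 81 -0.0390
0 65 82 0.3760
0 66 66 0.0000
0 66 78 0.2990
0 66 81 -0.0470
0 71 75 -0.0958
0 72 73 0.4500
0 76 76 0.0000
0 76 78 0.4000
0 78 78 0.0000
1 78 78 0.0000
0 78 79 -0.3030
0 78 81 -0.3500
0 79 81 -0.0430
0 80 81 -0.4000
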