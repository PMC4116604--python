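# default stretch-bend couplings keyed by periodic-table rows of i,j,k (H=0, C-F=1, ...)
# columns: row_i row_j row_k kba_ijk kba_kji
0 1 0 0.15 0.15
0 1 1 0.10 0.30
0 1 2 0.05 0.35
0 1 3 0.05 0.35
0 1 4 0.05 0.35
0 2 0 0.00 0.00
0 2 1 0.00 0.15
0 2 2 0.00 0.15
0 2 3 0.00 0.15
0 2 4 0.00 0.15
1 1 1 0.30 0.30
1 1 2 0.30 0.50
1 1 3 0.30 0.50
1 1 4 0.30 0.50
2 1 2 0.50 0.50
2 1 3 0.50 0.50
2 1 4 0.50 0.50
3 1 3 0.50 0.50
3 1 4 0.50 0.50
4 1 4 0.50 0.50
1 2 1 0.30 0.30
1 2 2 0.25 0.25
1 2 3 0.25 0.25
1 2 4 0.25 0.25
2 2 2 0.25 0.25
2 2 3 0.25 0.25
2 2 4 0.25 0.25
3 2 3 0.25 0.25
3 2 4 0.25 0.25
4 2 4 0.25 0.25
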