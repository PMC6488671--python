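length_diff_pct,identity_pct,diagonals_pct
0.30,99.20,0.15
0.20,99.30,0.14
0.40,98.00,0.16
0.30,98.10,0.15
0.10,95.90,0.18
0.23,97.30,0.17
0.34,98.20,0.16
0.35,96.40,0.18
0.70,99.00,0.4
1.20,99.00,0.3
5.80,75.00,6.2
25,50.00,20
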