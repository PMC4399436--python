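# Representative 10 MV photon fluence spectrum (user-replaceable)
# energy_MeV,weight
0.25,0.012
0.50,0.055
0.75,0.080
1.00,0.095
1.50,0.125
2.00,0.125
2.50,0.110
3.00,0.095
3.50,0.080
4.00,0.065
5.00,0.060
6.00,0.040
7.00,0.026
8.00,0.016
9.00,0.009
10.00,0.007
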