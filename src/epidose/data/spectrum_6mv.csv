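# Representative 6 MV photon fluence spectrum (user-replaceable)
# energy_MeV,weight
0.25,0.020
0.50,0.085
0.75,0.115
1.00,0.125
1.25,0.120
1.50,0.110
2.00,0.130
2.50,0.095
3.00,0.070
3.50,0.050
4.00,0.035
4.50,0.022
5.00,0.013
5.50,0.007
6.00,0.003
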