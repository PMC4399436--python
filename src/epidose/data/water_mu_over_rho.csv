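# Mass attenuation coefficient of liquid water (NIST XCOM values)
# energy_MeV,mu_over_rho_cm2_per_g
0.010,5.329
0.015,1.673
0.020,0.8096
0.030,0.3756
0.040,0.2683
0.050,0.2269
0.060,0.2059
0.080,0.1837
0.100,0.1707
0.150,0.1505
0.200,0.1370
0.300,0.1186
0.400,0.1061
0.500,0.09687
0.600,0.08956
0.800,0.07865
1.000,0.07072
1.250,0.06323
1.500,0.05754
2.000,0.04942
3.000,0.03969
4.000,0.03403
5.000,0.03031
6.000,0.02770
8.000,0.02429
10.000,0.02219
15.000,0.01941
20.000,0.01813
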