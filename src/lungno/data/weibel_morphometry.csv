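generation,L_cm,Omega_cm2,OmegaPrime_cm2
0,12.00,1.83,1.83
1,4.76,1.68,1.68
2,1.90,1.54,1.54
3,0.76,1.44,1.44
4,1.26,1.79,1.79
5,1.06,2.24,2.24
6,0.90,2.86,2.86
7,0.76,3.68,3.68
8,0.64,5.02,5.02
9,0.54,6.90,6.90
10,0.46,9.67,9.67
11,0.38,14.15,14.15
12,0.32,20.79,20.79
13,0.26,33.56,33.56
14,0.20,50.13,50.13
15,0.20,81.56,81.56
16,0.16,130,130
17,0.14,249,217
18,0.12,530,385
19,0.1,1140,683
20,0.08,3069,1155
21,0.06,6810,2324
22,0.06,15015,4244
23,0.06,30155,8516
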