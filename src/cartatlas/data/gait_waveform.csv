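stance_pct,axial_force_bw,flexion_deg
0,0.40,5.0
5,1.00,10.0
10,1.80,15.0
15,2.30,18.0
20,2.60,17.0
25,2.50,15.0
30,2.20,12.0
35,2.00,9.0
40,1.90,7.0
45,1.85,5.0
50,1.90,4.0
55,2.00,4.0
60,2.20,5.0
65,2.50,6.0
70,2.70,8.0
75,2.60,10.0
80,2.20,14.0
85,1.60,20.0
90,1.00,28.0
95,0.50,36.0
100,0.30,42.0
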