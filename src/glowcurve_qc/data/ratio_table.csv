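l4_over_l3,l3_over_l1,l3_over_l2,l1_over_l4,energy_kev,beam
0.8,7.80,2.10,0.15,20,NS 25
0.92,3.19,1.47,0.34,24,NS30
0.95,1.50,1.15,0.70,33,NS40
0.96,1.04,1.03,1.00,48,NS60
0.97,0.94,0.99,1.09,65,NS80
0.97,0.93,1.00,1.11,83,NS100
0.98,0.96,1.00,1.06,100,NS120
0.96,0.96,1.01,1.09,118,NS150
0.98,0.94,1.01,1.09,164,NS200
0.97,0.93,1.03,1.10,208,NS250
0.97,0.89,0.97,1.16,250,NS300
1.02,0.97,1.03,1.01,118,H150
0.79,8.88,2.90,0.14,20,M30
0.93,1.96,1.35,0.55,35,M60
0.96,1.14,1.08,0.92,53,M100
0.98,0.97,1.01,1.05,73,M150
0.96,1.41,1.15,0.74,38,S60
1.00,1.00,1.00,1.00,662,Cs137
0.00,6200,6200,0.05,,Tl204
0.30,4.98,67.5,0.68,,Sr90/Y90
0.23,6.44,24.2,0.69,,DU
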