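# published 2-D anisotropy function F(r,theta) for the double-encapsulated
# Yb-169 HDR prototype; empty cells are voxels shadowed by the drive cable
# stated uncertainty: 0.03 everywhere except the theta=90 normalization row
theta_deg,r0.5,r1.0,r2.0,r3.0,r4.0,r5.0,r6.0,r7.0
0,0.55,0.55,0.62,0.69,0.65,0.75,0.73,0.72
10,0.55,0.58,0.63,0.71,0.68,0.78,0.76,0.74
20,0.68,0.70,0.73,0.78,0.77,0.83,0.82,0.81
30,0.79,0.81,0.82,0.85,0.84,0.88,0.87,0.86
40,0.87,0.88,0.88,0.90,0.90,0.92,0.92,0.91
50,0.93,0.92,0.93,0.94,0.93,0.95,0.95,0.94
60,0.96,0.96,0.96,0.97,0.96,0.97,0.97,0.97
70,0.98,0.98,0.98,0.98,0.98,0.99,0.99,0.99
80,1.00,1.00,1.00,1.00,1.00,1.00,1.00,0.99
90,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00
100,0.99,1.00,0.99,1.00,1.00,1.00,1.00,1.00
110,0.97,0.98,0.99,0.99,0.99,0.99,0.99,0.99
120,0.95,0.97,0.96,0.97,0.97,0.98,0.98,0.98
130,0.92,0.93,0.93,0.95,0.94,0.96,0.96,0.96
140,0.86,0.88,0.89,0.92,0.90,0.93,0.93,0.92
150,0.79,0.81,0.84,0.87,0.86,0.90,0.89,0.88
160,0.69,0.73,0.75,0.80,0.78,0.85,0.84,0.82
170,0.54,0.58,0.64,0.71,0.68,0.78,0.77,0.74
172,0.51,0.54,0.61,0.70,0.66,0.77,0.75,0.73
174,0.40,0.49,0.55,0.67,0.63,0.74,0.73,0.71
176,,0.45,0.53,0.64,0.60,0.73,0.70,0.67
178,,,0.45,0.59,0.54,0.71,0.66,0.63
180,,,0.33,0.52,0.47,0.64,0.62,0.57
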