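# published radial dose function values for Yb-169 HDR sources
# this_work: the double-encapsulated prototype; model_4140: commercial Yb-169 HDR
# model_m42_a / model_m42_b: two independent characterizations of the M42 design
r_cm,this_work,model_4140,model_m42_a,model_m42_b
0.5,0.960,0.970,0.945,0.965
1.0,1.000,1.000,1.000,1.000
2.0,1.070,1.070,1.081,1.071
3.0,1.120,1.120,1.131,1.129
4.0,1.140,1.150,1.158,1.167
5.0,1.150,1.170,1.168,1.195
6.0,1.150,1.160,1.165,1.210
7.0,1.140,1.150,1.151,1.194
8.0,1.110,1.120,1.128,1.159
9.0,1.090,1.090,1.098,1.122
10.0,1.060,1.050,1.062,1.086
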