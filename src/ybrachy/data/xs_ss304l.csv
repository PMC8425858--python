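# material=ss304l density_g_cm3=8.0
# provenance: analytic cross-section model (scripts/generate_xs_tables.py): Klein-Nishina incoherent, empirical coherent fit, photoelectric anchored to published elemental attenuation coefficients
energy_keV,mu_pe,mu_incoh,mu_coh,mu_total,mu_en
10,165.883366,0.0307645656,1.46995464,167.384085,130.005483
11.0691999,125.933059,0.039301025,1.21194552,127.184306,101.319389
12.2527186,95.5916753,0.0484590754,0.999222629,96.639357,78.7081194
13.5627791,72.5485729,0.0579543112,0.823837249,73.4303644,60.9696147
15.0129113,55.0451212,0.0675082353,0.679235831,55.7918653,47.1066429
16.6180916,41.439346,0.0768688856,0.560015118,42.07623,36.0392616
18.3948978,31.1849521,0.0858236594,0.461720242,31.732496,27.5134747
19.999,24.6699319,0.0927698873,0.393902014,25.1566038,21.9987936
20.001,25.056491,0.0927779322,0.39382718,25.5430961,22.0822279
20.36168,23.8120394,0.0942050492,0.380678262,24.2869227,21.0352662
22.5387506,17.818778,0.101890835,0.313860918,18.2345298,15.940878
24.9485936,13.3228898,0.108800505,0.258771477,13.6904617,12.0546801
27.6160969,9.95057481,0.114889522,0.213351435,10.2788158,9.09589319
30.5688097,7.42142196,0.120142723,0.175903601,7.71746828,6.84725127
33.8372265,5.52510493,0.124567745,0.14502868,5.79470136,5.14129139
37.4551023,4.10322649,0.128189037,0.119572981,4.35098851,3.84853931
41.4598014,3.04440537,0.131042748,0.0985853132,3.27403344,2.87694441
45.8926829,2.25897313,0.133172584,0.081281439,2.47342715,2.15038237
50.799528,1.66998408,0.134626594,0.0670147724,1.87162545,1.60157274
56.231013,1.2379734,0.135454809,0.0552522172,1.42868043,1.19672203
62.2432322,0.917799748,0.135707569,0.0455542472,1.09906156,0.895122583
68.8982779,0.684184482,0.135434422,0.0375584825,0.857177387,0.674206608
76.264881,0.502896591,0.134683449,0.0309661491,0.668546189,0.502043156
84.4191212,0.372171195,0.133500897,0.0255309141,0.531203006,0.377663748
93.4452126,0.276135111,0.131931023,0.0210496814,0.429115815,0.286199798
103.436374,0.205552441,0.130016057,0.0173550029,0.352923501,0.219011129
114.49579,0.158790111,0.127796236,0.0143088211,0.300895168,0.174744068
126.737678,0.119457897,0.125309841,0.0117973107,0.256565049,0.137485579
140.288469,0.0864697651,0.122593233,0.00972662518,0.218789623,0.106237803
155.288111,0.0623925422,0.119680841,0.00801939017,0.190092773,0.0835816839
171.891513,0.0479920516,0.116605125,0.00661181216,0.171208989,0.0703265317
190.270152,0.0353684266,0.113396496,0.00545129482,0.154216218,0.0587131198
210.613835,0.0266972979,0.110083218,0.0044944736,0.14127499,0.050902538
233.132663,0.021144804,0.106691302,0.00370559539,0.131541701,0.0460840275
258.059205,0.0161870715,0.103244411,0.00305518252,0.122486666,0.0417658874
285.650892,0.0117790359,0.0997638001,0.0025189313,0.114061767,0.0379049815
316.192682,0.0087489641,0.0962682873,0.00207680388,0.107094055,0.0353248812
350,0.00683794154,0.092774292,0.00171227947,0.101324513,0.0337720387
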