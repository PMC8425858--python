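# material=titanium density_g_cm3=4.54
# provenance: analytic cross-section model (scripts/generate_xs_tables.py): Klein-Nishina incoherent, empirical coherent fit, photoelectric anchored to published elemental attenuation coefficients
energy_keV,mu_pe,mu_incoh,mu_coh,mu_total,mu_en
10,109.525781,0.0398841626,1.13433517,110.7,98.6834767
11.0691999,82.486389,0.0490519476,0.935234593,83.4706755,75.1100386
12.2527186,62.1094438,0.0585332115,0.77108051,62.9390576,57.0924338
13.5627791,46.7538915,0.0680537693,0.635739051,47.4576843,43.34285
15.0129113,35.1809688,0.0773676818,0.524152972,35.7824895,32.8631573
16.6180916,26.2994438,0.0862691093,0.432152685,26.8178656,24.7353094
18.3948978,19.6482604,0.0945972338,0.356300457,20.0991581,18.5939618
20.36168,14.6622196,0.102235862,0.29376195,15.0582174,13.9530786
22.5387506,10.9111155,0.109109491,0.242200316,11.2624253,10.4362409
24.9485936,8.10858922,0.115177409,0.199688874,8.4234555,7.79190847
27.6160969,6.01505127,0.120427082,0.164639119,6.30011747,5.80524081
30.5688097,4.4555798,0.124867655,0.13574136,4.71618881,4.31788868
33.8372265,3.30383376,0.12852409,0.111915789,3.54427363,3.21460783
37.4551023,2.43986069,0.13143221,0.092272125,2.66356503,2.38367839
41.4598014,1.8003107,0.133634697,0.0760763531,2.01002175,1.76653739
45.8926829,1.33051552,0.135178023,0.0627232927,1.52841684,1.31197142
50.799528,0.977630694,0.136110204,0.0517139858,1.16545488,0.969708381
56.231013,0.723080047,0.136479241,0.0426370526,0.902196342,0.722476953
62.2432322,0.534819322,0.136332108,0.0351533193,0.70630475,0.539457107
68.8982779,0.399353477,0.135714163,0.0289831445,0.564050784,0.407789734
76.264881,0.291882783,0.134668857,0.0238959701,0.45044761,0.303305423
84.4191212,0.215188481,0.133237654,0.0197017058,0.368127841,0.228913006
93.4452126,0.159390058,0.131460072,0.0162436264,0.307093756,0.174977794
103.436374,0.118211828,0.129373779,0.0133925154,0.260978122,0.135368977
114.49579,0.0921468581,0.127014711,0.0110418367,0.230203405,0.110626702
126.737678,0.0695367479,0.124417163,0.00910375333,0.203057664,0.0892261205
140.288469,0.0499932796,0.121613842,0.00750584592,0.179112967,0.0707892468
155.288111,0.0356268511,0.118635865,0.00618840614,0.160451122,0.0574177695
171.891513,0.0274724043,0.115512713,0.0051022058,0.148087323,0.0501480244
190.270152,0.0201974391,0.112272139,0.00420665732,0.136676235,0.0436827044
210.613835,0.0151775624,0.108940048,0.00346829715,0.127585907,0.0393888377
233.132663,0.0120126326,0.105540375,0.0028595353,0.120412543,0.036868182
258.059205,0.0091899022,0.102094966,0.00235762444,0.113642492,0.0346136341
285.650892,0.00668577999,0.0986234898,0.00194380989,0.10725308,0.0326001391
316.192682,0.00494736652,0.0951433983,0.00160262883,0.101693394,0.0312724528
350,0.00384842165,0.091669933,0.00132133249,0.0968396872,0.0305047037
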