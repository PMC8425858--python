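# material=ss316l density_g_cm3=8.02
# provenance: analytic cross-section model (scripts/generate_xs_tables.py): Klein-Nishina incoherent, empirical coherent fit, photoelectric anchored to published elemental attenuation coefficients
energy_keV,mu_pe,mu_incoh,mu_coh,mu_total,mu_en
10,165.523774,0.0302086945,1.50365172,167.057634,129.489001
11.0691999,125.663889,0.0386585935,1.23972802,126.942276,100.939374
12.2527186,95.3901991,0.0477457701,1.02212869,96.4600736,78.428382
13.5627791,72.3977718,0.0571894413,0.8427228,73.297684,60.7635888
15.0129113,54.9322655,0.066712508,0.694806555,55.6937845,46.9548358
16.6180916,41.3560909,0.0760624515,0.57285284,42.0050062,35.9284855
18.3948978,31.1235534,0.0850246466,0.472304664,31.6808827,27.4326462
19.999,24.6221556,0.0919885281,0.402931779,25.1170759,21.9364348
20.001,26.1950546,0.0919965995,0.402855229,26.6899065,22.2893519
20.36168,24.8973876,0.0934286519,0.389404887,25.3802212,21.2491919
22.5387506,18.645554,0.101148909,0.32105583,19.0677587,16.1709347
24.9485936,13.9526274,0.108101564,0.264703524,14.3254325,12.2759058
27.6160969,10.4301811,0.11423901,0.218242278,10.7626624,9.29592012
30.5688097,7.78640019,0.119543447,0.179935995,8.08587963,7.02103865
33.8372265,5.80199417,0.124020367,0.148353301,6.07436783,5.28772348
37.4551023,4.31327481,0.127692575,0.122314059,4.56328144,3.96962845
41.4598014,3.20414827,0.130595029,0.100845272,3.43558857,2.97589283
45.8926829,2.38102852,0.132770636,0.0831447255,2.59694388,2.23070234
50.799528,1.7631188,0.134266965,0.0685510114,1.96593678,1.66610812
56.231013,1.30852889,0.135133819,0.0565188127,1.50018152,1.24777403
62.2432322,0.971304529,0.135421495,0.0465985275,1.15332455,0.935310988
68.8982779,0.724825167,0.135179636,0.0384194689,0.898424272,0.705725751
76.264881,0.53375474,0.134456506,0.0316760136,0.69988726,0.526673064
84.4191212,0.396061389,0.133298595,0.0261161818,0.555476165,0.397220668
93.4452126,0.2949525,0.131750429,0.0215322219,0.448235152,0.301952167
103.436374,0.220385174,0.129854524,0.017752847,0.367992545,0.231671605
114.49579,0.170484177,0.127651394,0.0146368349,0.312772406,0.184886486
126.737678,0.128648586,0.125179592,0.0120677509,0.265895929,0.145574024
140.288469,0.093667331,0.12247573,0.00994959722,0.226092658,0.11265764
155.288111,0.0680826823,0.119574469,0.00820322575,0.195860377,0.0887171718
171.891513,0.0525839682,0.116508481,0.00676338059,0.17585583,0.0745108765
190.270152,0.0390483172,0.113308363,0.00557625968,0.15793294,0.062095375
210.613835,0.0296804253,0.110002546,0.0045975044,0.144280476,0.0536645308
233.132663,0.0235881948,0.106617188,0.00379054203,0.133995925,0.0483599505
258.059205,0.0181675705,0.10317608,0.00312521917,0.12446887,0.0436199657
285.650892,0.0133634159,0.0997005868,0.002576675,0.115640678,0.0393941923
316.192682,0.0100368032,0.096209623,0.0021244123,0.108370838,0.0365391448
350,0.00790292309,0.0927196898,0.00175153157,0.102374144,0.0347784583
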