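# material=air density_g_cm3=0.0012
# provenance: analytic cross-section model (scripts/generate_xs_tables.py): Klein-Nishina incoherent, empirical coherent fit, photoelectric anchored to published elemental attenuation coefficients
energy_keV,mu_pe,mu_incoh,mu_coh,mu_total,mu_en
10,4.73947243,0.134705886,0.240513035,5.11469135,4.742
11.0691999,3.44737155,0.184288878,0.198297748,3.82995818,3.45118247
12.2527186,2.50724451,0.197246121,0.163492165,2.8679828,2.51173775
13.5627791,1.82326298,0.189612488,0.134795722,2.14767119,1.82801883
15.0129113,1.32564226,0.171957573,0.111136131,1.60873597,1.33038864
16.6180916,0.960188815,0.191663831,0.0916293142,1.24348196,0.966007291
18.3948978,0.695058887,0.190838672,0.0755463696,0.961443929,0.701426679
20.36168,0.503021465,0.185768765,0.0622863329,0.751076563,0.509829936
22.5387506,0.364293497,0.199777526,0.051353722,0.615424745,0.372329736
24.9485936,0.263109692,0.199557189,0.042340023,0.505006904,0.271913089
27.6160969,0.189360975,0.190696522,0.0349084248,0.414965922,0.198578627
30.5688097,0.136217107,0.180664516,0.0287812344,0.345662858,0.145776542
33.8372265,0.0989606885,0.181966986,0.0237294996,0.304657175,0.109489727
37.4551023,0.0709464684,0.178607874,0.0195644545,0.269118796,0.082235456
41.4598014,0.0509134698,0.17443379,0.0161304657,0.241477726,0.062942489
45.8926829,0.0369194266,0.172381978,0.0132992169,0.222600621,0.0498729607
50.799528,0.0260996908,0.169130677,0.0109649141,0.206195282,0.0399299846
56.231013,0.0190222731,0.16648046,0.00904033233,0.194543065,0.0338155632
62.2432322,0.0137575063,0.163449201,0.00745355669,0.184660264,0.0295162328
68.8982779,0.0104269121,0.160376536,0.00614529481,0.176948743,0.0271773272
76.264881,0.00725176442,0.157336222,0.00506666144,0.169654648,0.0250237595
84.4191212,0.00508236709,0.154060944,0.00417735178,0.163320662,0.023869811
93.4452126,0.00370208789,0.15061753,0.00344413537,0.157763753,0.0234961313
103.436374,0.00259249574,0.147107219,0.00283961444,0.152539329,0.0233879014
114.49579,0.00205520913,0.143326894,0.00234120013,0.147723303,0.0238074571
126.737678,0.00153228611,0.139604229,0.00193026841,0.143066784,0.0242345392
140.288469,0.00102851225,0.135943873,0.00159146417,0.13856385,0.0246692828
155.288111,0.000630167193,0.132200199,0.00131212747,0.134142494,0.0251656682
171.891513,0.000431248244,0.128227564,0.00108182046,0.129740633,0.0257784881
190.270152,0.000287644261,0.124304597,0.00089193736,0.125484179,0.026406231
210.613835,0.000151365213,0.12030447,0.000735382886,0.121191219,0.0269671008
233.132663,2.55452764e-05,0.116248816,0.000606307139,0.116880668,0.0274592002
258.059205,1e-08,0.11222354,0.000499887003,0.112723437,0.0279602795
285.650892,1e-08,0.108301918,0.000412145923,0.108714074,0.0284705026
316.192682,1e-08,0.104336716,0.000339805318,0.104676532,0.0288591883
350,1e-08,0.100355596,0.000280162068,0.100635768,0.0291300602
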