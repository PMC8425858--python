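# material=yb2o3 density_g_cm3=6.2
# provenance: analytic cross-section model (scripts/generate_xs_tables.py): Klein-Nishina incoherent, empirical coherent fit, photoelectric anchored to published elemental attenuation coefficients
energy_keV,mu_pe,mu_incoh,mu_coh,mu_total,mu_en
10,171.34084,0.0149228519,5.0091903,176.364954,171.34112
11.0691999,144.033869,0.0168456997,4.12996807,148.180683,144.034217
12.2527186,121.082738,0.0192620963,3.40506853,124.507069,121.083177
13.5627791,101.790795,0.0223314121,2.80740469,104.620531,101.791355
15.0129113,85.5204446,0.026168746,2.31464389,87.8612573,85.521167
16.6180916,66.8436271,0.0308193766,1.90837337,68.7828199,66.8445627
18.3948978,52.2375256,0.0362481532,1.57341219,53.847186,52.2387352
20.36168,40.6914892,0.0423446298,1.29724401,42.0310778,40.6930411
22.5387506,31.2426623,0.0489402187,1.06954937,32.3611519,31.244631
24.9485936,23.978482,0.0558315192,0.881820114,24.9161336,23.9809449
27.6160969,18.394224,0.062804158,0.727041437,19.1840696,18.3972598
30.5688097,14.0919316,0.0696530682,0.599429797,14.7610145,14.0956171
33.8372265,10.7545432,0.0761971194,0.494216784,11.3249571,10.7589521
37.4551023,8.19950225,0.0822877239,0.407470952,8.68926092,8.20470328
41.4598014,6.25945805,0.0878121617,0.335950906,6.68322112,6.26551361
45.8926829,4.79357711,0.0926929082,0.27698419,5.16325421,4.80054246
50.799528,3.65818468,0.0968843439,0.228367419,3.98343645,3.66610719
56.231013,2.75970977,0.100368055,0.188283953,3.04836178,2.76862837
61.331,2.20195859,0.102786749,0.159652397,2.46439774,2.21175275
61.333,11.0015313,0.102787562,0.159642506,11.2639614,2.33892269
62.2432322,10.5918537,0.103147651,0.15523601,10.8502374,2.37445119
68.8982779,8.14980139,0.105243726,0.127988702,8.38303381,2.44182947
76.264881,6.26539591,0.10668933,0.105523891,6.47760913,2.30546897
84.4191212,4.8181835,0.107526124,0.087002145,5.01271177,2.0718062
93.4452126,3.70492422,0.107801254,0.0717313697,3.88445684,1.80214999
103.436374,2.83938953,0.107564895,0.0591409487,3.00609537,1.52738536
114.49579,2.16405228,0.106868375,0.0487604214,2.31968107,1.26644537
126.737678,1.64476183,0.105762771,0.0402019032,1.79072651,1.03450884
140.288469,1.24564436,0.104297886,0.0331455917,1.38308784,0.834489874
155.288111,0.944841703,0.1025215,0.027327817,1.07469102,0.669698226
171.891513,0.721378071,0.100478839,0.0225311886,0.844388099,0.53833738
190.270152,0.547195655,0.0982121904,0.0185764733,0.663984318,0.428790048
210.613835,0.418667036,0.0957606503,0.0153158968,0.529743583,0.343904579
233.132663,0.322799624,0.0931599536,0.0126276226,0.4285872,0.277839434
258.059205,0.246260219,0.0904423915,0.0104111992,0.347113809,0.222674944
285.650892,0.185259496,0.0876368009,0.00858380652,0.281480103,0.176952723
316.192682,0.141630065,0.0847686238,0.00707716113,0.23347585,0.143443657
350,0.110035821,0.0818600308,0.00583496488,0.197730816,0.118649593
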