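# material=water density_g_cm3=0.998
# provenance: analytic cross-section model (scripts/generate_xs_tables.py): Klein-Nishina incoherent, empirical coherent fit, photoelectric anchored to published elemental attenuation coefficients
energy_keV,mu_pe,mu_incoh,mu_coh,mu_total,mu_en
10,4.94128193,0.144858461,0.242990469,5.32913086,4.944
11.0691999,3.58318167,0.196291026,0.200340338,3.97981303,3.58724077
12.2527186,2.59798984,0.21163055,0.165176236,2.97479662,2.60281075
13.5627791,1.88334946,0.206677791,0.136184202,2.22621146,1.88853335
15.0129113,1.36495157,0.191779199,0.112280902,1.66901167,1.37024507
16.6180916,0.985520632,0.211026126,0.092573153,1.28911991,0.991926902
18.3948978,0.711038545,0.210446182,0.0763245441,0.997809271,0.718060588
20.36168,0.512874924,0.206161616,0.0629279208,0.78196446,0.520430798
22.5387506,0.370440386,0.220496957,0.0518826972,0.642820041,0.379310085
24.9485936,0.266743312,0.220165848,0.0427761515,0.529685312,0.276455853
27.6160969,0.191286235,0.211132851,0.0352680033,0.437687089,0.201491713
30.5688097,0.137066783,0.201115313,0.0290776989,0.367259795,0.147708324
33.8372265,0.0993720093,0.202384529,0.0239739281,0.325730466,0.111082455
37.4551023,0.0709851137,0.198610334,0.0197659805,0.289361428,0.0835383653
41.4598014,0.0507506514,0.194037296,0.0162966195,0.261084567,0.0641315356
45.8926829,0.0367224965,0.19170938,0.0134362071,0.241868083,0.0511283759
50.799528,0.025834295,0.188050203,0.0110778595,0.224962358,0.0412116919
56.231013,0.0187972813,0.185139692,0.00913345336,0.213070427,0.0352486124
62.2432322,0.0135485672,0.181771497,0.00753033295,0.202850397,0.0310738124
68.8982779,0.010270905,0.178337159,0.00620859516,0.194816659,0.0288972048
76.264881,0.00711911094,0.17488255,0.0051188512,0.187120512,0.0268730606
84.4191212,0.00496610373,0.171221021,0.00422038109,0.180407506,0.025846187
93.4452126,0.0036116378,0.167420222,0.0034796121,0.174511472,0.0256138785
103.436374,0.00251928777,0.163520367,0.00286886423,0.168908519,0.0256348926
114.49579,0.00197951732,0.159379318,0.00236531594,0.163724151,0.0261679885
126.737678,0.0014670009,0.155241527,0.00195015137,0.15865868,0.0267121705
140.288469,0.0009890015,0.151112835,0.00160785724,0.153709694,0.0272676691
155.288111,0.000612794016,0.146902413,0.0013256432,0.14884085,0.0278769308
171.891513,0.000415995633,0.142494119,0.00109296389,0.144003078,0.0285833607
190.270152,0.000290351797,0.138100459,0.000901124868,0.139291936,0.0293076923
210.613835,0.00015515201,0.133660248,0.000742957786,0.134558358,0.029947876
233.132663,1.21754234e-05,0.129196477,0.000612552479,0.129821205,0.0305013597
258.059205,1e-08,0.124716388,0.000505036149,0.125221434,0.0310650728
285.650892,1e-08,0.120340752,0.000416391282,0.120757153,0.0316392041
316.192682,1e-08,0.115927631,0.000343305524,0.116270946,0.0320772367
350,1e-08,0.111505101,0.000283047912,0.111788159,0.0323832679
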