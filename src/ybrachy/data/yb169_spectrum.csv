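energy_keV,intensity_pct,uncertainty_pct
49.77,53.2,2.50
50.74,94.0,2.30
57.60,29.5,2.50
59.10,8.2,2.70
63.10,44.2,0.60
93.62,2.6,0.04
109.78,17.5,0.18
118.19,1.9,0.018
130.52,11.3,0.09
177.21,22.2,0.18
197.96,35.8,0.30
261.08,1.7,0.011
307.74,10.1,0.07
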