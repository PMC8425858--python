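{
  "yb2o3": {
    "name": "yb2o3",
    "density_g_cm3": 6.2,
    "composition": {"Yb": 0.8782, "O": 0.1218},
    "note": "ytterbia ceramic active core"
  },
  "titanium": {
    "name": "titanium",
    "density_g_cm3": 4.54,
    "composition": {"Ti": 1.0},
    "note": "inner capsule tube"
  },
  "ss316l": {
    "name": "ss316l",
    "density_g_cm3": 8.02,
    "composition": {"Cr": 0.1721043, "Fe": 0.6977581, "Ni": 0.1017542, "Cu": 0.0036561, "Mo": 0.0252361},
    "note": "outer capsule tube; raw weight percents sum to 100.05, normalized on load"
  },
  "ss304l": {
    "name": "ss304l",
    "density_g_cm3": 8.00,
    "composition": {"Cr": 0.1903956, "Fe": 0.7182345, "Ni": 0.0832419, "Cu": 0.0022653, "Mo": 0.0062862},
    "note": "drive cable"
  },
  "water": {
    "name": "water",
    "density_g_cm3": 0.998,
    "composition": {"H": 0.111894, "O": 0.888106},
    "note": "phantom medium at 22 C"
  },
  "air": {
    "name": "air",
    "density_g_cm3": 0.0012,
    "composition": {"H": 0.000732, "C": 0.000123, "N": 0.750325, "O": 0.236077, "Ar": 0.012743},
    "note": "air at 40% relative humidity for kerma-strength tallies"
  }
}
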