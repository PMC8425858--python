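{
  "name": "yb169-hdr-double-capsule-prototype",
  "active_length_cm": 0.26,
  "active_diameter_cm": 0.048,
  "external_diameter_cm": 0.090,
  "total_length_cm": 0.473,
  "cable_diameter_cm": 0.090,
  "cable_length_cm": 2.0,
  "core_material": "yb2o3",
  "cable_material": "ss304l",
  "layers": [
    {"material": "titanium", "radial_thickness_cm": 0.006, "endcap_thickness_cm": 0.006},
    {"material": "ss316l", "radial_thickness_cm": 0.015, "endcap_thickness_cm": 0.015}
  ],
  "note": "Double-encapsulated Yb-169 HDR source: ytterbia ceramic core inside a laser-welded Ti tube inside an SS 316L tube with a hemispherical distal tip; SS 304L drive cable on the proximal side. theta = 0 deg points through the distal tip, 180 deg toward the cable. The nominal 0.60 mm core diameter cannot coexist with the 0.90 mm external diameter and the 0.06 + 0.15 mm walls, so the default core fills the interior left by the walls (0.48 mm); every dimension is a config field."
}
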