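{
 "meta": {
  "name": "bowie-environment-thresholds",
  "note": "side-chain environment classes from buried area (A^2) and polar-covered fraction; combined with helix/sheet/other secondary structure this yields the 18 classes",
  "units": {"buried_area": "A^2", "polar_fraction": "dimensionless"}
 },
 "buried_area": {"exposed_max": 40.0, "partial_max": 114.0},
 "polar_fraction": {"partial_split": 0.67, "buried_split_1": 0.45, "buried_split_2": 0.58},
 "classes": ["E", "P1", "P2", "B1", "B2", "B3"],
 "secondary": ["helix", "sheet", "other"]
}
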