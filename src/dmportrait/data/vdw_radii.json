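{
 "meta": {
  "name": "bondi-1964-extended",
  "units": "angstrom",
  "note": "element-based van der Waals radii (Bondi, with common extensions); 'default' is used for elements not listed"
 },
 "radii": {
  "H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8,
  "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
  "NA": 2.27, "K": 2.75, "CA": 2.31, "MG": 1.73, "ZN": 1.39,
  "FE": 2.0, "MN": 2.0, "CU": 1.4, "SE": 1.9,
  "default": 1.8
 }
}
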