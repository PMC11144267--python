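{
 "meta": {
  "context": "central residue of Gly-X-Gly tripeptide",
  "generator": "rdkit 2024.09.2",
  "mol_logp_GGG_with_H": -2.7379,
  "scheme": "wildman-crippen-1999",
  "units": "octanol-water logP contribution per heavy atom, implicit-hydrogen folded"
 },
 "residues": {
  "ALA": {
   "C": -0.2783,
   "CA": -0.0821,
   "CB": 0.5131,
   "N": -0.4954,
   "O": -0.1526
  },
  "ARG": {
   "C": -0.2783,
   "CA": -0.0821,
   "CB": 0.3901,
   "CD": 0.0425,
   "CG": 0.3901,
   "CZ": -0.2783,
   "N": -0.4954,
   "NE": -0.4954,
   "NH1": 0.2981,
   "NH2": -0.5906,
   "O": -0.1526
  },
  "ASN": {
   "C": -0.2783,
   "CA": -0.0821,
   "CB": 0.3901,
   "CG": -0.2783,
   "N": -0.4954,
   "ND2": -0.5906,
   "O": -0.1526,
   "OD1": -0.1526
  },
  "ASP": {
   "C": -0.2783,
   "CA": -0.0821,
   "CB": 0.3901,
   "CG": -0.2783,
   "N": -0.4954,
   "O": -0.1526,
   "OD1": -0.1526,
   "OD2": 0.0087
  },
  "CYS": {
   "C": -0.2783,
   "CA": -0.0821,
   "CB": 0.0425,
   "N": -0.4954,
   "O": -0.1526,
   "SG": 0.3805
  },
  "GLN": {
   "C": -0.2783,
   "CA": -0.0821,
   "CB": 0.3901,
   "CD": -0.2783,
   "CG": 0.3901,
   "N": -0.4954,
   "NE2": -0.5906,
   "O": -0.1526,
   "OE1": -0.1526
  },
  "GLU": {
   "C": -0.2783,
   "CA": -0.0821,
   "CB": 0.3901,
   "CD": -0.2783,
   "CG": 0.3901,
   "N": -0.4954,
   "O": -0.1526,
   "OE1": -0.1526,
   "OE2": 0.0087
  },
  "GLY": {
   "C": -0.2783,
   "CA": 0.0425,
   "N": -0.4954,
   "O": -0.1526
  },
  "HIS": {
   "C": -0.2783,
   "CA": -0.0821,
   "CB": 0.1944,
   "CD2": 0.2811,
   "CE1": 0.2811,
   "CG": 0.136,
   "N": -0.4954,
   "ND1": -0.3239,
   "NE2": -0.1097,
   "O": -0.1526
  },
  "ILE": {
   "C": -0.2783,
   "CA": -0.0821,
   "CB": 0.123,
   "CD1": 0.5131,
   "CG1": 0.5131,
   "CG2": 0.3901,
   "N": -0.4954,
   "O": -0.1526
  },
  "LEU": {
   "C": -0.2783,
   "CA": -0.0821,
   "CB": 0.3901,
   "CD1": 0.5131,
   "CD2": 0.5131,
   "CG": 0.123,
   "N": -0.4954,
   "O": -0.1526
  },
  "LYS": {
   "C": -0.2783,
   "CA": -0.0821,
   "CB": 0.3901,
   "CD": 0.3901,
   "CE": 0.0425,
   "CG": 0.3901,
   "N": -0.4954,
   "NZ": -0.5906,
   "O": -0.1526
  },
  "MET": {
   "C": -0.2783,
   "CA": -0.0821,
   "CB": 0.3901,
   "CE": 0.1655,
   "CG": 0.0425,
   "N": -0.4954,
   "O": -0.1526,
   "SD": 0.6482
  },
  "PHE": {
   "C": -0.2783,
   "CA": -0.0821,
   "CB": 0.1944,
   "CD1": 0.2811,
   "CD2": 0.2811,
   "CE1": 0.2811,
   "CE2": 0.2811,
   "CG": 0.136,
   "CZ": 0.2811,
   "N": -0.4954,
   "O": -0.1526
  },
  "PRO": {
   "C": -0.2783,
   "CA": -0.0821,
   "CB": 0.3901,
   "CD": 0.0425,
   "CG": 0.3901,
   "N": -0.3187,
   "O": -0.1526
  },
  "SER": {
   "C": -0.2783,
   "CA": -0.0821,
   "CB": 0.0425,
   "N": -0.4954,
   "O": -0.1526,
   "OG": -0.557
  },
  "THR": {
   "C": -0.2783,
   "CA": -0.0821,
   "CB": -0.0821,
   "CG2": 0.5131,
   "N": -0.4954,
   "O": -0.1526,
   "OG1": -0.557
  },
  "TRP": {
   "C": -0.2783,
   "CA": -0.0821,
   "CB": 0.1944,
   "CD1": 0.2811,
   "CD2": 0.2955,
   "CE2": 0.2955,
   "CE3": 0.2811,
   "CG": 0.136,
   "CH2": 0.2811,
   "CZ2": 0.2811,
   "CZ3": 0.2811,
   "N": -0.4954,
   "NE1": -0.1097,
   "O": -0.1526
  },
  "TYR": {
   "C": -0.2783,
   "CA": -0.0821,
   "CB": 0.1944,
   "CD1": 0.2811,
   "CD2": 0.2811,
   "CE1": 0.2811,
   "CE2": 0.2811,
   "CG": 0.136,
   "CZ": 0.5437,
   "N": -0.4954,
   "O": -0.1526,
   "OH": -0.557
  },
  "VAL": {
   "C": -0.2783,
   "CA": -0.0821,
   "CB": 0.123,
   "CG1": 0.5131,
   "CG2": 0.5131,
   "N": -0.4954,
   "O": -0.1526
  }
 },
 "terminal": {
  "OXT": 0.0087
 }
}
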