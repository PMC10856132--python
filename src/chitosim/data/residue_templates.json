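{
 "comment": "Idealized rigid chitosan residue templates; local frame: +z chain axis, +y amine side, ring centroid at origin.",
 "rise_per_monomer": 5.2,
 "residues": {
  "GlcN": {
   "C1": [
    0.25,
    0.0,
    1.43
   ],
   "C2": [
    -0.25,
    1.238,
    0.715
   ],
   "C3": [
    0.25,
    1.238,
    -0.715
   ],
   "C4": [
    -0.25,
    0.0,
    -1.43
   ],
   "C5": [
    0.25,
    -1.238,
    -0.715
   ],
   "O5": [
    -0.25,
    -1.238,
    0.715
   ],
   "O4": [
    -0.25,
    0.84,
    -2.6
   ],
   "N": [
    -0.25,
    2.511,
    1.45
   ],
   "HN1": [
    -0.25,
    3.514,
    1.57
   ],
   "O3": [
    0.25,
    2.477,
    -1.43
   ],
   "HO3": [
    0.25,
    3.427,
    -1.564
   ],
   "C6": [
    1.0,
    -2.45,
    -1.165
   ],
   "O6": [
    0.6,
    -3.8,
    -0.966
   ],
   "HO6": [
    1.272,
    -4.486,
    -0.966
   ],
   "H61": [
    1.98,
    -2.18,
    -1.55
   ],
   "H62": [
    1.16,
    -2.76,
    -2.2
   ],
   "H1": [
    1.33,
    0.1,
    1.56
   ],
   "H2": [
    -1.34,
    1.238,
    0.715
   ],
   "H3": [
    1.34,
    1.238,
    -0.715
   ],
   "H4": [
    -1.34,
    0.0,
    -1.43
   ],
   "H5": [
    1.34,
    -1.238,
    -0.715
   ],
   "HN2": [
    0.58,
    2.861,
    0.98
   ]
  },
  "GlcNAc": {
   "C1": [
    0.25,
    0.0,
    1.43
   ],
   "C2": [
    -0.25,
    1.238,
    0.715
   ],
   "C3": [
    0.25,
    1.238,
    -0.715
   ],
   "C4": [
    -0.25,
    0.0,
    -1.43
   ],
   "C5": [
    0.25,
    -1.238,
    -0.715
   ],
   "O5": [
    -0.25,
    -1.238,
    0.715
   ],
   "O4": [
    -0.25,
    0.84,
    -2.6
   ],
   "N": [
    -0.25,
    2.511,
    1.45
   ],
   "HN1": [
    -0.25,
    3.37,
    0.918
   ],
   "O3": [
    0.25,
    2.477,
    -1.43
   ],
   "HO3": [
    0.25,
    3.427,
    -1.564
   ],
   "C6": [
    1.0,
    -2.45,
    -1.165
   ],
   "O6": [
    0.6,
    -3.8,
    -0.966
   ],
   "HO6": [
    1.272,
    -4.486,
    -0.966
   ],
   "H61": [
    1.98,
    -2.18,
    -1.55
   ],
   "H62": [
    1.16,
    -2.76,
    -2.2
   ],
   "H1": [
    1.33,
    0.1,
    1.56
   ],
   "H2": [
    -1.34,
    1.238,
    0.715
   ],
   "H3": [
    1.34,
    1.238,
    -0.715
   ],
   "H4": [
    -1.34,
    0.0,
    -1.43
   ],
   "H5": [
    1.34,
    -1.238,
    -0.715
   ],
   "C7": [
    -0.25,
    3.535,
    2.314
   ],
   "O7": [
    -0.25,
    4.69,
    1.9
   ],
   "C8": [
    0.96,
    3.005,
    3.04
   ],
   "H81": [
    0.84,
    1.935,
    3.21
   ],
   "H82": [
    1.85,
    3.18,
    2.43
   ],
   "H83": [
    1.06,
    3.52,
    3.99
   ]
  }
 },
 "terminal": {
  "HO4": [
   -0.25,
   1.62,
   -3.17
  ],
  "O1": [
   0.25,
   0.42,
   2.76
  ],
  "HO1": [
   0.25,
   1.0,
   3.52
  ]
 },
 "heavy_bonds": {
  "GlcN": [
   [
    "C1",
    "C2"
   ],
   [
    "C2",
    "C3"
   ],
   [
    "C3",
    "C4"
   ],
   [
    "C4",
    "C5"
   ],
   [
    "C5",
    "O5"
   ],
   [
    "O5",
    "C1"
   ],
   [
    "C2",
    "N"
   ],
   [
    "C3",
    "O3"
   ],
   [
    "C4",
    "O4"
   ],
   [
    "C5",
    "C6"
   ],
   [
    "C6",
    "O6"
   ]
  ],
  "GlcNAc": [
   [
    "C1",
    "C2"
   ],
   [
    "C2",
    "C3"
   ],
   [
    "C3",
    "C4"
   ],
   [
    "C4",
    "C5"
   ],
   [
    "C5",
    "O5"
   ],
   [
    "O5",
    "C1"
   ],
   [
    "C2",
    "N"
   ],
   [
    "C3",
    "O3"
   ],
   [
    "C4",
    "O4"
   ],
   [
    "C5",
    "C6"
   ],
   [
    "C6",
    "O6"
   ],
   [
    "N",
    "C7"
   ],
   [
    "C7",
    "O7"
   ],
   [
    "C7",
    "C8"
   ]
  ]
 }
}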