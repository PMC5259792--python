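{
  "comment": "GAFF-like 12-6 Lennard-Jones parameters (sigma in Angstrom, epsilon in kcal/mol) for the atom types of the reduced chloroarene-amide dimer. 'c3u' is a united-atom methyl (OPLS-UA flavored); 'ep' is the massless sigma-hole extra point and carries no LJ.",
  "types": {
    "ca": {"sigma": 3.3997, "epsilon": 0.086, "description": "aromatic carbon"},
    "ha": {"sigma": 2.5996, "epsilon": 0.015, "description": "aromatic hydrogen"},
    "cl": {"sigma": 3.4709, "epsilon": 0.265, "description": "aryl chlorine"},
    "c":  {"sigma": 3.3997, "epsilon": 0.086, "description": "amide carbonyl carbon"},
    "o":  {"sigma": 2.9599, "epsilon": 0.210, "description": "amide carbonyl oxygen"},
    "n":  {"sigma": 3.2500, "epsilon": 0.170, "description": "amide nitrogen"},
    "hn": {"sigma": 1.0691, "epsilon": 0.0157, "description": "amide hydrogen"},
    "c3u": {"sigma": 3.7750, "epsilon": 0.207, "description": "united-atom methyl"},
    "ep": {"sigma": 0.0, "epsilon": 0.0, "description": "sigma-hole extra point"},
    "occ": {"sigma": 5.0, "epsilon": 0.1, "repulsive": true, "description": "helix-context occluder (sterics only)"}
  }
}
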