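{
  "version": "2016.1",
  "comment": "Element-keyed atomic property tables. m: standard atomic mass (u); e: Pauling electronegativity; vdw_radius: Bondi van der Waals radius (Angstrom), from which the volume v = 4/3*pi*r^3 is derived; p: static dipole polarizability (Angstrom^3); r: covalent radius (Angstrom); h: coarse Crippen-style atomic logP (hydrophobicity) contribution; s: chemical softness 1/(I-A) (eV^-1); a: coarse atomic molar refractivity contribution (a_H is the per-hydrogen increment added for suppressed hydrogens).",
  "m": {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
        "P": 30.974, "S": 32.06, "Cl": 35.45, "Br": 79.904, "I": 126.904},
  "e": {"H": 2.20, "C": 2.55, "N": 3.04, "O": 3.44, "F": 3.98,
        "P": 2.19, "S": 2.58, "Cl": 3.16, "Br": 2.96, "I": 2.66},
  "vdw_radius": {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
                 "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98},
  "p": {"H": 0.667, "C": 1.76, "N": 1.10, "O": 0.802, "F": 0.557,
        "P": 3.63, "S": 2.90, "Cl": 2.18, "Br": 3.05, "I": 5.35},
  "r": {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
        "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39},
  "h": {"H": 0.123, "C": 0.144, "N": -0.600, "O": -0.250, "F": 0.220,
        "P": -0.500, "S": 0.255, "Cl": 0.650, "Br": 0.860, "I": 0.590},
  "s": {"H": 0.0778, "C": 0.1000, "N": 0.0691, "O": 0.0822, "F": 0.0713,
        "P": 0.1025, "S": 0.1208, "Cl": 0.1068, "Br": 0.1185, "I": 0.1355},
  "a": {"H": 1.03, "C": 2.75, "N": 2.47, "O": 1.58, "F": 0.92,
        "P": 6.92, "S": 7.37, "Cl": 5.85, "Br": 8.74, "I": 14.00},
  "default_valence": {"H": 1, "C": 4, "N": 3, "O": 2, "F": 1,
                      "P": 3, "S": 2, "Cl": 1, "Br": 1, "I": 1}
}
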