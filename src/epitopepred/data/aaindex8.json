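{
  "_comment": "Eight cluster-central 'high-quality' AAindex indices (fuzzy-clustering representatives of the AAindex database), transcribed from AAindex. Keys are AAindex accessions; values map each standard residue to the index value.",
  "indices": {
    "BLAM930101": {
      "A": 0.96, "C": 0.42, "D": 0.42, "E": 0.53, "F": 0.59,
      "G": 0.0, "H": 0.57, "I": 0.84, "K": 0.73, "L": 0.92,
      "M": 0.86, "N": 0.39, "P": -2.5, "Q": 0.8, "R": 0.77,
      "S": 0.53, "T": 0.54, "V": 0.63, "W": 0.58, "Y": 0.72
    },
    "BIOV880101": {
      "A": 16.0, "C": 168.0, "D": -78.0, "E": -106.0, "F": 189.0,
      "G": -13.0, "H": 50.0, "I": 151.0, "K": -141.0, "L": 145.0,
      "M": 124.0, "N": -74.0, "P": -20.0, "Q": -73.0, "R": -70.0,
      "S": -70.0, "T": -38.0, "V": 123.0, "W": 145.0, "Y": 53.0
    },
    "MAXF760101": {
      "A": 1.43, "C": 0.94, "D": 0.92, "E": 1.67, "F": 1.19,
      "G": 0.46, "H": 0.98, "I": 1.04, "K": 1.27, "L": 1.36,
      "M": 1.53, "N": 0.64, "P": 0.49, "Q": 1.22, "R": 1.18,
      "S": 0.7, "T": 0.78, "V": 0.98, "W": 1.01, "Y": 0.69
    },
    "TSAJ990101": {
      "A": 89.3, "C": 102.5, "D": 114.4, "E": 138.8, "F": 190.8,
      "G": 63.8, "H": 157.5, "I": 163.0, "K": 165.1, "L": 163.1,
      "M": 165.8, "N": 122.4, "P": 121.6, "Q": 146.9, "R": 190.3,
      "S": 94.2, "T": 119.6, "V": 138.2, "W": 226.4, "Y": 194.6
    },
    "NAKH920108": {
      "A": 9.36, "C": 2.56, "D": 0.94, "E": 0.94, "F": 10.99,
      "G": 6.17, "H": 0.47, "I": 13.73, "K": 0.58, "L": 16.64,
      "M": 3.93, "N": 2.31, "P": 1.96, "Q": 1.14, "R": 0.27,
      "S": 5.58, "T": 4.68, "V": 12.43, "W": 2.2, "Y": 3.13
    },
    "CEDJ970104": {
      "A": 7.9, "C": 1.9, "D": 5.5, "E": 7.1, "F": 3.9,
      "G": 7.1, "H": 2.1, "I": 5.2, "K": 6.7, "L": 8.6,
      "M": 2.4, "N": 4.0, "P": 5.3, "Q": 4.4, "R": 4.9,
      "S": 6.6, "T": 5.3, "V": 6.8, "W": 1.2, "Y": 3.1
    },
    "LIFS790101": {
      "A": 0.92, "C": 1.16, "D": 0.48, "E": 0.61, "F": 1.25,
      "G": 0.61, "H": 0.93, "I": 1.81, "K": 0.7, "L": 1.3,
      "M": 1.19, "N": 0.6, "P": 0.4, "Q": 0.95, "R": 0.93,
      "S": 0.82, "T": 1.12, "V": 1.81, "W": 1.54, "Y": 1.53
    },
    "MIYS990104": {
      "A": -0.04, "C": -0.38, "D": 0.19, "E": 0.23, "F": -0.38,
      "G": 0.09, "H": -0.04, "I": -0.34, "K": 0.33, "L": -0.37,
      "M": -0.3, "N": 0.13, "P": 0.19, "Q": 0.14, "R": 0.07,
      "S": 0.12, "T": 0.03, "V": -0.29, "W": -0.33, "Y": -0.29
    }
  }
}
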