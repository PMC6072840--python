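{
  "_comment": "Canonical three-group residue partitions for the seven physicochemical properties of the composition-transition-distribution (CTD) descriptor, after the Dubchak protein-fold-class encoding. Each property partitions the 20 standard residues into 3 disjoint covering groups; group order is fixed and defines feature order.",
  "properties": [
    {
      "name": "hydrophobicity",
      "groups": [
        ["polar", "RKEDQN"],
        ["neutral", "GASTPHY"],
        ["hydrophobic", "CLVIMFW"]
      ]
    },
    {
      "name": "vdw_volume",
      "groups": [
        ["small", "GASCTPD"],
        ["medium", "NVEQIL"],
        ["large", "MHKFRYW"]
      ]
    },
    {
      "name": "polarity",
      "groups": [
        ["low", "LIFWCMVY"],
        ["medium", "PATGS"],
        ["high", "HQRKNED"]
      ]
    },
    {
      "name": "polarizability",
      "groups": [
        ["low", "GASDT"],
        ["medium", "CPNVEQIL"],
        ["high", "KMHFRYW"]
      ]
    },
    {
      "name": "charge",
      "groups": [
        ["positive", "KR"],
        ["neutral", "ANCQGHILMFPSTWYV"],
        ["negative", "DE"]
      ]
    },
    {
      "name": "secondary_structure",
      "groups": [
        ["helix", "EALMQKRH"],
        ["strand", "VIYCWFT"],
        ["coil", "GNPSD"]
      ]
    },
    {
      "name": "solvent_accessibility",
      "groups": [
        ["buried", "ALFCGIVW"],
        ["exposed", "RKQEND"],
        ["intermediate", "MSPTHY"]
      ]
    }
  ]
}
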