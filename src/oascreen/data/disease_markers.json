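{
  "IVA": {
    "full_name": "Isovaleric aciduria",
    "omim": "243500",
    "biomarkers": ["Isovalerylglycine", "3-Hydroxyisovaleric acid"]
  },
  "MCADD": {
    "full_name": "Medium-chain acyl-CoA dehydrogenase deficiency",
    "omim": "201450",
    "biomarkers": ["Hexanoylglycine", "Suberylglycine", "Phenylpropionylglycine"]
  },
  "PA": {
    "full_name": "Propionic aciduria",
    "omim": "606054",
    "biomarkers": ["Propionylglycine", "2-Methylcitric acid", "3-Hydroxypropionic acid", "Tiglylglycine"]
  },
  "GA1": {
    "full_name": "Glutaric aciduria type I",
    "omim": "231670",
    "biomarkers": ["3-Hydroxyglutaric acid", "Glutaric acid"]
  },
  "MMA": {
    "full_name": "Methylmalonic aciduria (mut0)",
    "omim": "251000",
    "biomarkers": ["Methylmalonic acid", "2-Methylcitric acid"]
  },
  "MSUD": {
    "full_name": "Maple syrup urine disease",
    "omim": "248600",
    "biomarkers": ["2-Hydroxy-3-methylpentanoic acid", "2-Hydroxy-3-methylbutyric acid", "3-Methyl-2-oxovaleric acid", "alpha-Ketoisovaleric acid"]
  },
  "OXOPRO": {
    "full_name": "5-Oxoprolinuria (pyroglutamic aciduria)",
    "omim": "266130",
    "biomarkers": ["Pyroglutamic acid"]
  },
  "MADD": {
    "full_name": "Glutaric aciduria type II (multiple acyl-CoA dehydrogenase deficiency)",
    "omim": "231680",
    "biomarkers": ["Ethylmalonic acid", "Glutaric acid", "2-Hydroxyglutaric acid", "Adipic acid", "Suberic acid", "Hexanoylglycine"]
  }
}
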