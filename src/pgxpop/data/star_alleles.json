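{
  "comment": "Standard star-allele definitions restricted to the panel's assay sites. defining_states map rsid -> required allele on that haplotype; tag_rsid is the variant that tags the allele for frequency derivation. *1 is the implicit default (empty states). Activity values follow the bundled rule tables; see phenotype_rules.json.",
  "genes": {
    "CYP2C9": [
      {"name": "*2", "function_class": "decreased", "activity_value": 0.5,
       "tag_rsid": "rs1799853", "defining_states": {"rs1799853": "T"}},
      {"name": "*3", "function_class": "none", "activity_value": 0.0,
       "tag_rsid": "rs1057910", "defining_states": {"rs1057910": "C"}}
    ],
    "CYP2C19": [
      {"name": "*2", "function_class": "none", "activity_value": 0.0,
       "tag_rsid": "rs4244285", "defining_states": {"rs4244285": "A"}},
      {"name": "*3", "function_class": "none", "activity_value": 0.0,
       "tag_rsid": "rs4986893", "defining_states": {"rs4986893": "A"}},
      {"name": "*4", "function_class": "none", "activity_value": 0.0,
       "tag_rsid": "rs28399504", "defining_states": {"rs28399504": "G"}},
      {"name": "*17", "function_class": "increased", "activity_value": 1.5,
       "tag_rsid": "rs12248560", "defining_states": {"rs12248560": "T"}}
    ],
    "CYP2D6": [
      {"name": "*3", "function_class": "none", "activity_value": 0.0,
       "tag_rsid": "rs35742686", "defining_states": {"rs35742686": "del"}},
      {"name": "*4", "function_class": "none", "activity_value": 0.0,
       "tag_rsid": "rs3892097",
       "defining_states": {"rs3892097": "T", "rs1065852": "A"}},
      {"name": "*6", "function_class": "none", "activity_value": 0.0,
       "tag_rsid": "rs5030655", "defining_states": {"rs5030655": "del"}},
      {"name": "*9", "function_class": "decreased", "activity_value": 0.25,
       "tag_rsid": "rs5030656", "defining_states": {"rs5030656": "CT"}},
      {"name": "*41", "function_class": "decreased", "activity_value": 0.5,
       "tag_rsid": "rs28371725", "defining_states": {"rs28371725": "T"}},
      {"name": "*10", "function_class": "decreased", "activity_value": 0.25,
       "tag_rsid": "rs1065852", "defining_states": {"rs1065852": "A"}}
    ]
  }
}
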