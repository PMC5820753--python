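{
  "comment": "Fourteen stereogenic C-H center types, each defined by the multiset of its three non-H substituent type labels. Matching ignores order.",
  "types": {
    "A": ["phenyl", "reversed_secondary_amide", "ester"],
    "B": ["phenyl", "reversed_secondary_amide", "primary_amide"],
    "C": ["five_membered_aromatic", "reversed_secondary_amide", "ester"],
    "D": ["alkyl", "reversed_secondary_amide", "acidic_secondary_amide"],
    "E": ["phenyl", "reversed_secondary_amide", "acidic_secondary_amide"],
    "F": ["alkyl", "aminothiooxo_imide", "acidic_secondary_amide"],
    "G": ["alkyl", "reversed_secondary_thioamide", "acidic_secondary_amide"],
    "H": ["ketone", "dialkyl_tertiary_amine", "alkyl"],
    "I": ["ketone", "primary_amine", "alkyl"],
    "J": ["carboxylic_acid", "five_membered_aromatic", "alkyl"],
    "K": ["thioether", "alkyl", "acidic_secondary_amide"],
    "L": ["imide", "alkyl", "acidic_secondary_amide"],
    "M": ["phenyl", "phenyl", "five_membered_aromatic"],
    "N": ["ester", "dialkyl_tertiary_amine", "phenyl"]
  },
  "aromatic_anion_overrides": {}
}
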