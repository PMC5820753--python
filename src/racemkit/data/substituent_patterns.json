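{
  "provenance": "built-in rule set covering the substituent types named in the center-type catalogue; extend or override with a user pattern file of the same schema",
  "comment": "Rules are applied in file order; the first match wins, so more specific environments (imide before amide, thiourea-type N before generic thioamide N, acid before ester before ketone) come first. Each SMARTS is a single-atom recursive pattern matched against the neighbor atom as seen from the stereocenter.",
  "rules": [
    {
      "rule_id": "aminothiooxo_imide_n",
      "smarts": "[NX3;$([NX3][CX3](=[SX1])[NX3])]",
      "type_label": "aminothiooxo_imide",
      "delocalizing": false
    },
    {
      "rule_id": "imide_n",
      "smarts": "[NX3;$([NX3]([CX3]=[OX1])[CX3]=[OX1])]",
      "type_label": "imide",
      "delocalizing": false
    },
    {
      "rule_id": "reversed_secondary_thioamide_n",
      "smarts": "[NX3;H1;$([NX3][CX3]=[SX1])]",
      "type_label": "reversed_secondary_thioamide",
      "delocalizing": false
    },
    {
      "rule_id": "acidic_secondary_amide_c",
      "smarts": "[CX3;$([CX3](=[OX1])[NX3;H1])]",
      "type_label": "acidic_secondary_amide",
      "delocalizing": true
    },
    {
      "rule_id": "reversed_secondary_amide_n",
      "smarts": "[NX3;H1;$([NX3][CX3]=[OX1])]",
      "type_label": "reversed_secondary_amide",
      "delocalizing": false
    },
    {
      "rule_id": "carboxylic_acid_c",
      "smarts": "[CX3;$([CX3](=[OX1])[OX2H1]),$([CX3](=[OX1])[OX1-])]",
      "type_label": "carboxylic_acid",
      "delocalizing": true
    },
    {
      "rule_id": "ester_c",
      "smarts": "[CX3;$([CX3](=[OX1])[OX2][#6])]",
      "type_label": "ester",
      "delocalizing": true
    },
    {
      "rule_id": "primary_amide_c",
      "smarts": "[CX3;$([CX3](=[OX1])[NX3;H2])]",
      "type_label": "primary_amide",
      "delocalizing": true
    },
    {
      "rule_id": "ketone_c",
      "smarts": "[CX3;$([CX3](=[OX1])[#6])]",
      "type_label": "ketone",
      "delocalizing": true
    },
    {
      "rule_id": "dialkyl_tertiary_amine_n",
      "smarts": "[NX3;H0;!$([NX3][CX3]=[OX1]);!$([NX3][CX3]=[SX1]);$([NX3]([#6])([#6])[#6])]",
      "type_label": "dialkyl_tertiary_amine",
      "delocalizing": false
    },
    {
      "rule_id": "primary_amine_n",
      "smarts": "[NX3;H2;!$([NX3][CX3]=[OX1]);!$([NX3][CX3]=[SX1])]",
      "type_label": "primary_amine",
      "delocalizing": false
    },
    {
      "rule_id": "thioether_s",
      "smarts": "[SX2;$([SX2]([#6])[#6])]",
      "type_label": "thioether",
      "delocalizing": false
    },
    {
      "rule_id": "phenyl_c",
      "smarts": "[c;$(c1ccccc1)]",
      "type_label": "phenyl",
      "delocalizing": true
    },
    {
      "rule_id": "five_membered_aromatic_a",
      "smarts": "[a;r5]",
      "type_label": "five_membered_aromatic",
      "delocalizing": true
    },
    {
      "rule_id": "alkyl_c",
      "smarts": "[CX4;!$([CX4][F,Cl,Br,I])]",
      "type_label": "alkyl",
      "delocalizing": false
    }
  ]
}
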