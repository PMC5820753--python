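type_label,ddg_kcal_mol,delocalizing,provenance
alkyl,-2.0,false,provisional
phenyl,-12.0,true,provisional
five_membered_aromatic,-14.0,true,provisional
ester,-16.0,true,provisional
ketone,-18.0,true,provisional
carboxylic_acid,-12.0,true,provisional
primary_amide,-13.0,true,provisional
acidic_secondary_amide,-14.0,true,provisional
reversed_secondary_amide,-8.0,false,provisional
reversed_secondary_thioamide,-12.0,false,provisional
aminothiooxo_imide,-13.0,false,provisional
imide,-10.0,false,provisional
dialkyl_tertiary_amine,-5.0,false,provisional
primary_amine,-4.0,false,provisional
thioether,-7.0,false,provisional
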