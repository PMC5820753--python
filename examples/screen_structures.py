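"""Screen structures for racemization-prone stereocenters straight from SMILES.

Each molecule is searched for carbon stereocenters bearing exactly one
hydrogen; the three non-H substituents are classified, summed into a
group-contribution score (using the shipped provisional table), and mapped
to a physiological risk.  Whether the deprotonated center would form a
cyclic aromatic anion decides which calibration line is used.

The shipped contribution table is provisional, so treat the absolute
percentages here as illustrative; the classification and ranking machinery
is what this example demonstrates.
"""

from racemkit import MoleculeRecord, analyze_molecule, predict_molecule

COMPOUNDS = [
    ("thalidomide", "O=C1CCC(N2C(=O)c3ccccc3C2=O)C(=O)N1"),
    ("5-methylhydantoin", "CC1NC(=O)NC1=O"),
    ("N-acetyl phenylglycine methyl ester", "CC(=O)NC(c1ccccc1)C(=O)OC"),
    ("2-butanol (no acidic alpha-H environment)", "CCC(C)O"),
]

for name, smiles in COMPOUNDS:
    record = MoleculeRecord.from_smiles(smiles, name)
    reports = analyze_molecule(record)
    print(f"\n{name}")
    if not reports:
        print("  no one-hydrogen stereogenic carbon found")
        continue
    for rep in reports:
        labels = ", ".join(rep.type_labels)
        print(
            f"  atom {rep.atom_index}: [{labels}] -> center type {rep.center_type_code}"
            f"  (aromatic anion: {rep.aromatic_anion})"
        )
    for row in predict_molecule(record):
        print(
            f"  sigma_ddG = {row['sigma_ddg']:.1f} kcal/mol, "
            f"log k_gb = {row['log_kgb']:.2f}, "
            f"racemized in 24 h = {row['pct_racemized']}% -> {row['risk']} risk"
        )
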