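"""Predict physiological racemization from precomputed group-contribution scores.

Four literature compounds with known sigma-ddG scores (kcal/mol) are pushed
through the non-aromatic calibration line and the blood-equivalent exposure
scenario (0.15 M phosphate, pH 7.2, 24 h).  The printed percentage is the
predicted loss of enantiomeric excess within a day in the bloodstream — a
value above a few percent means an enantioselective synthesis of the
compound buys very little.
"""

from racemkit import predict_from_energy

for sigma_ddg in (-48.8, -50.7, -54.1, -46.9):
    row = predict_from_energy(sigma_ddg, domain="gc_nonaromatic")
    print(
        f"sigma_ddG = {sigma_ddg:6.1f} kcal/mol  ->  log k_gb = {row['log_kgb']:6.3f}  "
        f"half-life = {row['half_life_h']:6.1f} h  racemized in 24 h = "
        f"{row['pct_racemized']:4.1f}%  ({row['risk']} risk)"
    )
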