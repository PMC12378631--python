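"""Ligand bookkeeping: monoisotopic [M+H]+ masses, pIC50, fold potencies.

Parses Hill-notation formulas of protonated species, computes the
monoisotopic masses that HRMS characterization lines print as "calcd",
converts IC50 values to pIC50, and expresses potency losses as integer
fold changes.
"""

from contactsar import fold_ratio, monoisotopic_mass, parse_formula, pic50

compounds = {
    "cmpd28": ("C27H35N4O6S2", None),
    "cmpd34": ("C25H33N4O5S2", 59.0),
    "cmpd37": ("C25H31N4O6S2", 64.0),
    "cmpd38": ("C25H31N4O6S2", 906.0),
    "cmpd39": ("C25H31N4O6S2", 2950.0),
}

print(f"{'compound':<8} {'formula [M+H]+':<16} {'mass (Da)':>10} {'IC50 (nM)':>10} {'pIC50':>7}")
for name, (formula, ic50) in compounds.items():
    mass = monoisotopic_mass(parse_formula(formula))
    p = f"{pic50(ic50):7.4f}" if ic50 else "      -"
    ic = f"{ic50:10.0f}" if ic50 else "         -"
    print(f"{name:<8} {formula:<16} {mass:10.4f} {ic} {p}")

print()
print("meta vs ortho carboxylate isomer:", fold_ratio(906.0, 64.0), "fold less potent")
print("para vs ortho carboxylate isomer:", fold_ratio(2950.0, 64.0), "fold less potent")
print()
print("The mass column is the theoretical monoisotopic mass of the printed")
print("protonated formula; pIC50 = -log10(IC50 in mol/L), so higher = more potent.")
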