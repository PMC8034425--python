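"""Drug-likeness descriptors and the rule-of-five verdict.

Loads the packaged structure of NSC765598 (a fluorinated salicylanilide
derivative), computes the graph-derivable descriptors, and checks the
Lipinski rules using an externally predicted logP and molar refractivity.
"""

from screenkit.descriptors import compute_descriptors, lipinski
from screenkit.molgraph import load_fixture, parse_formula, format_formula

mol = load_fixture("nsc765598")
print(f"{mol.name}: {format_formula(mol.formula_counts())}")
assert mol.formula_counts() == parse_formula("C19H11F4NO2")

d = compute_descriptors(mol, logp=4.867901, molar_refractivity=87.77)
print(f"molecular weight : {d.mw} g/mol")
print(f"H-bond donors    : {d.n_hbd}   (phenolic O-H + amide N-H)")
print(f"H-bond acceptors : {d.n_hba}   (N + O; the four fluorines are excluded)")
print(f"TPSA             : {d.tpsa} A^2")
print(f"fraction Csp3    : {d.frac_csp3}  (all 19 carbons aromatic or carbonyl)")
print(f"rotatable bonds  : {d.n_rotatable}")

verdict = lipinski(d)
print(f"rule of five     : {'pass' if verdict.passed else verdict.violations}")

# Expected output: MW 361.29, HBD 2, HBA 3, TPSA 49.33, fraction Csp3 0.0,
# 4 rotatable bonds, and a clean rule-of-five pass -- the profile of an
# orally plausible small-molecule lead.
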