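"""Physical constants and unit conventions.

All lengths are in Å, charges in elementary charges (e), energies in
kcal/mol.  With these units the Coulomb energy between two charges is
``COULOMB_K * q1 * q2 / r`` — the CHARMM convention, which is what the
force-field parameter tables assume.
"""

#: Coulomb constant, kcal·Å/(mol·e²) (CHARMM convention).
COULOMB_K = 332.0636

#: Boltzmann constant, kcal/(mol·K).
KB = 0.0019872041

#: Simulation / analysis temperature, K.
TEMPERATURE = 300.0

#: kT at the analysis temperature, kcal/mol.
KT = KB * TEMPERATURE

#: ln(10) * kT — converts pH units to kcal/mol at 300 K.
KT_LN10 = 2.302585092994046 * KT

#: Avogadro's number / 1e27 — converts mol/L to number density in Å⁻³.
MOLAR_TO_PER_A3 = 6.02214076e-4
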