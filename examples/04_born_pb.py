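"""Finite-difference Poisson-Boltzmann vs the Born closed form.

Solves the linearized PB equation for a unit charge of radius 2 Å
transferred from a uniform dielectric of 1 into water (eps 80), using a
four-step electrostatic focusing ladder (grid spacing 2 -> 0.25 Å).
The analytic Born solvation energy is -(k q^2 / 2r)(1 - 1/eps_w) =
-81.98 kcal/mol; the focused finite-difference estimate lands within 2%.
"""

from pbsalink import synth
from pbsalink.pb import GridSpec, reaction_field_energy

structure, analytic = synth.born_fixture(q=1.0, radius=2.0)
ladder = [GridSpec((0, 0, 0), 65, h) for h in (2.0, 1.0, 0.5, 0.25)]
w = reaction_field_energy(structure, [0], ladder, eps_protein=1.0,
                          eps_solvent=80.0, ionic_strength_mM=0.0)
err = 100 * abs(w - analytic) / abs(analytic)
print(f"FDPB (focused 2->0.25 Å): {w:8.2f} kcal/mol")
print(f"Born closed form:         {analytic:8.2f} kcal/mol")
print(f"relative error:           {err:8.2f} %")
print("\nEach focusing step halves the grid spacing near the ion; the")
print("self-energy cancels because both dielectric environments use the")
print("identical grid and charge spreading.")
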