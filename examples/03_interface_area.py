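"""Buried interface area of the miniature intermediate trio.

The interface (buried) area is the solvent-accessible surface lost on
both faces upon complexation: B = SASA(A) + SASA(B) - SASA(AB).  The
ion-free model buries the most surface — the 'tighter' complex.
"""

import numpy as np

from pbsalink import surface, synth

trio = synth.make_trio(seed=0)
for name, s in trio.items():
    groups = [s.groups["A"], s.groups["LIG"]]
    if "ION" in s.groups:
        groups.append(s.groups["ION"])
    a = np.concatenate(groups)
    area = surface.interface_area(s, a, s.groups["B"])
    note = "(ion-free)" if name == "IIo" else f"(ion at {s.atoms[s.groups['ION'][0]].residue_name} site)"
    print(f"{name}: buried interface {area:6.1f} Å²  {note}")
print("\nLarger buried area correlates with the more stable, ion-free complex.")
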