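"""Four RMSD schemes on a jittered two-protein complex.

Builds a toy G-protein/GEF-like complex, generates a 50-frame ensemble
with 0.15 Å positional jitter plus a ±4° rigid rock of the partner, and
prints the four standard stability measures.  The cross-scheme value
(fit on A, measure B) isolates the relative orientation fluctuation and
is the largest — the signature of a complex whose partners move as
rigid bodies relative to each other.
"""

import numpy as np

from pbsalink import geometry, synth

toy = synth.make_toy_complex(synth.ToySpec(seed=1))
ens = synth.make_snapshot_ensemble(toy, 50, jitter_sd=0.15, rigid_rock_deg=4.0,
                                   seed=1)
ga, gb = toy.groups["A"], toy.groups["B"]
gall = np.concatenate([ga, gb])
ref = ens.frames[0]

print("scheme (fit | measure)      mean ± sd RMSD (Å)")
for label, (fit, measure) in {
    "complex | complex": (gall, gall),
    "A       | A      ": (ga, ga),
    "B       | B      ": (gb, gb),
    "A       | B      ": (ga, gb),
}.items():
    st = geometry.rmsd_series(ens, ref, fit, measure)
    print(f"  {label}   {st.mean:6.3f} ± {st.sd:5.3f}")

print("\nThe last row exceeds the third: the partner's own structure is")
print("stable but its orientation relative to A fluctuates.")
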