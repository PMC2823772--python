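# Methods

`pbsalink` implements the post-trajectory analysis stack used to
characterize small-GTPase / exchange-factor (GEF) complexes: trajectory
geometry, molecular-mechanics interaction energies, surface burial,
continuum electrostatics, snapshot MM-PBSA binding free energies, a
thermodynamic-cycle (linkage) estimate of divalent-ion affinity, and
multi-site pKa titration.  This note records the models, the defaults
and their rationale, the numerical choices, and what the synthetic test
bed does and does not demonstrate.

## Units and constants

Å for length, elementary charges for charge, kcal/mol for energy, ps for
time.  The Coulomb constant is fixed at 332.0636 kcal·Å/(mol·e²) and the
temperature at 300 K everywhere (kT = 0.596 kcal/mol; one pH unit =
1.3726 kcal/mol).  These are the CHARMM conventions, chosen so that
parameter tables and published energies can be used without conversion.

## Structures, parameters, trajectories

`model_io.ParameterizedStructure` holds ordered atoms with coordinates,
partial charge, Lennard-Jones parameters (well depth and half the
minimum-energy distance) and a continuum (PB) radius, plus named atom
groups.  PDB I/O is delegated to biotite; PQR and the package's plain
text *snapshot archive* (header + per-frame coordinate blocks written
with `%.17g`, hence exact float64 round trips) are written directly.
Parameter tables are plain TSV keyed by (residue, atom); two PB radius
columns support a standard and an "optimized" radius set, the latter
assigning 1.55 Å to Mg²⁺.  A GDP-like group, when present, must carry a
total charge of −3 e (asserted), matching the fully ionized nucleotide.
Internal atom indexing is 0-based; residue ids stay 1-based as in PDB.

## Trajectory geometry

Superposition is the least-squares rigid (Kabsch) transform, computed
via `scipy.spatial.transform.Rotation.align_vectors`; proper rotations
are enforced and collinear fit sets rejected.  Four RMSD schemes
summarize complex stability: fit/measure on the whole complex, on each
partner alone, and the cross scheme (fit on the G protein, measure the
GEF), which isolates inter-partner orientation fluctuations and is the
largest whenever the partners move as rigid bodies relative to each
other.  RMSF is the root-mean-square deviation of a target group's
centroid about its ensemble mean after per-frame fitting on a chosen
frame group (e.g. the ion in the nucleotide's coordinate system); it is
invariant to rigid motion of the fit group.  Ensemble statistics use all
supplied frames — equilibration trimming is the caller's job.

## Molecular-mechanics energies

Two nonbonded modes, never mixed implicitly:

* **trajectory mode** — Lennard-Jones plus *shifted-force* Coulomb,
  `E = k q_i q_j (1/r − 2/r_c + r/r_c²)` for `r ≤ r_c` (12 Å default),
  dielectric 1.  The shifted-force form is the standard choice whose
  energy and derivative vanish continuously at the cutoff; its exact
  functional form is a package decision since only the scheme name is
  conventionally reported.
* **MM-PBSA mode** — Lennard-Jones with no cutoff; electrostatics are
  handled entirely by the continuum solver.

Combining rules are CHARMM-style (geometric well depth, additive
rmin/2).  All analyzed pairs are intergroup, so no bonded exclusions or
1-4 scaling arise.  Per-residue decomposition follows from pairwise
additivity and is asserted to sum to the group-group total.

## Surface area

Shrake-Rupley with a deterministic golden-spiral quadrature (default 960
points, probe 1.4 Å, radii = PB radii).  The interface (buried) area is
`B = SASA(A) + SASA(B) − SASA(AB)` — both faces — which is what places
large protein-protein interfaces in the >3000 Å² range.  The nonpolar
solvation term is γ·SASA with γ = 0.0072 kcal/(mol·Å²) by default
(configurable), the value standard in snapshot MM-PBSA practice.

## Finite-difference Poisson-Boltzmann

The linearized PB equation `∇·(ε∇φ) − κ̄²φ = −4πk_c ρ` is discretized
with the 7-point stencil on uniform cubic grids: harmonic-mean
dielectrics on cell faces (a smoothed boundary without a legacy
smoother's exact recipe), trilinear charge spreading (total charge
conserved to 1e-9 e), screening κ̄² = 8πk_c I/kT in solvent and zero
inside any atom radius plus a 2 Å Stern layer, and Dirichlet boundary
values from a screened-Coulomb monopole sum.  The symmetric
positive-definite system is solved by Jacobi-preconditioned conjugate
gradients to a 1e-6 relative residual (1e4 iteration cap).  Only the
linearized equation is implemented: at 150 mM and moderate charge
densities the nonlinear corrections are small.

*Focusing* re-solves on finer sub-grids whose boundary values are
interpolated from the parent; charges outside a focused window are
dropped from the window's source term (they act through the boundary)
but energies are only ever evaluated on grids enclosing every source —
the solver refuses otherwise.

Charging work `W = ½Σqφ` contains a spreading-dependent self-energy, so
every physical quantity is a same-grid difference: the reaction-field
(solvation) energy is `W(ε_out=ε_w, salt) − W(ε_out=ε_p, no salt)`, and
the electrostatic binding term is
`ΔW_elec = ΔG_rf(AB) − ΔG_rf(A) − ΔG_rf(B) + E_coul(A,B)/ε_p`
with the inter-group Coulomb term evaluated analytically (no cutoff) and
identical coordinates/grids for complex and components (rigid-body
snapshot convention).  On the Born fixture (q = 1 e, r = 2 Å, ε 1→80)
the 2→0.25 Å focusing ladder lands within 2% of the −81.98 kcal/mol
closed form.  Difference-potential maps solve two models on one common
focused ladder and subtract node-wise; grids are written as OpenDX.

## Snapshot MM-PBSA and linkage

Per snapshot, `ΔG = E_vdW + ΔW_elec + ΔG_np`; entropy terms are omitted
by construction on the assumption that they cancel between the compared
species.  Ensemble estimates select snapshots by *time* stride from the
first frame and report per-component mean ± sd; both protein dielectrics
1 and 4 can be computed.  Model comparison is a two-sample t-test on
per-snapshot totals (pooled and Welch variants, also available from
summary statistics).  The linkage relation closes the four-state
thermodynamic cycle: the change in ion-binding free energy caused by GEF
binding equals ΔG(GEF binding, ion present) − ΔG(GEF binding, ion
absent); on the published per-model totals this yields shifts of ≈49 and
≈25 kcal/mol for the two ion placements.  (The published prose pairs
"25 and 49 ... respectively" with the opposite model order than the
table arithmetic gives; the package labels shifts by model and leaves
the prose ordering unresolved.)

## pKa titration

The classical FDPB recipe: model pKa (aqueous model compound) →
intrinsic pKa (FDPB shift with all other sites neutral) → pairwise
charged-charged couplings → statistical-mechanical titration.  The site
model is deliberately reduced: charged and neutral forms differ by
exactly ±1 e on the titratable atom, because published charge sets for
every variant are not reproducible from text sources; the model compound
is the site's own residue in water, so intra-residue interactions cancel
between the two environments.  The pKa protocol uses ε 20/80, 150 mM,
2 Å Stern and a focusing ladder (the classical four-step 2→0.25 Å ladder
on a 110-node cube is expressible directly; tests use smaller ladders).
An extra phosphate ionization centre (nucleotide O2B, model pKa 6.4) can
be added; in a salt-bridge environment its intrinsic pKa drops below 7,
consistent with a fully ionized (−3) nucleotide.

Titration curves are Boltzmann averages over ionization microstates with
energy `E(s) = Σ s_i ln10·kT(pH − pKa_i) + Σ_{i<j} W_ij z_i z_j`
(s = protonation, z = charge indicators): exact 2ⁿ enumeration up to 20
sites (pKa½ then by true bisection), Metropolis single-site flips beyond
(seed mandatory, 10³ equilibration + 10⁴ production sweeps default,
acceptance rate reported).  On 10-site fixtures the seeded MC reproduces
exact pKa½ within 0.05 pH units.

## Synthetic test bed

The generators are pure functions of spec + seed.  The toy complex is
two ~20-atom clusters at Lennard-Jones contact distance with a 3-atom
−3 e nucleotide-like ligand at the interface and optionally a +2 e ion
(PB radius 1.55 Å).  Interfacial chemistry is deterministic: cluster
positions are sorted interface-first and the atom-type cycle leads with
basic atoms, mirroring the basic residues that real exchange factors
present to the nucleotide; cluster atoms keep ≥3.2 Å from the pre-placed
ligand/ion sites so contacts are attractive rather than clashing.

The *miniature trio* (ion-free; canonical ion; displaced ion) emulates
the three modelled intermediate species.  In the ion-containing variants
the partner cluster is retracted 2.5 Å — the ion at the interfacial seam
prevents the partner's close approach — so the ion-free complex shows
both the lowest MM-PBSA ΔG (ion desolvation + like-charge repulsion
dominate) and the largest buried interface, the published qualitative
ranking.  This holds for every seed 0–24 at the default sizes.

What the synthetic ensembles do **not** emulate: real force-field
sampling, solvent structure, conformational transitions, polarization.
Passing tests therefore demonstrate the correctness of the estimators
(oracle equivalence, analytic limits, parameter recovery) and the
internal consistency of the published numbers — not the reproduction of
trajectory-derived statistics, which would require the original
multi-nanosecond simulations.

## Problem sizes and defaults

Defaults are sized for a single-CPU workflow: PB grids 33–65 nodes per
edge, SASA 960 quadrature points (0.5% convergence against 4000),
MM-PBSA auto-ladders of two focusing steps enclosing the complex with a
24 Å coarse margin, trio ensembles of a few snapshots.  All are
configurable; the classical full-scale protocols (110-node pKa grids,
100 snapshots at 40 ps) are expressible with the same interfaces.

## Known limitations

- The PB dielectric boundary is the union of atomic spheres (van der
  Waals surface) with harmonic face smoothing, not a molecular (solvent
  -excluded) surface; re-entrant crevices are treated as solvent.
- Single-atom ±1 e charge variants for titratable sites ignore charge
  redistribution within the group.
- No nonlinear PB, no conformational averaging for pKa, no entropy
  estimates, no bonded MM terms.
- DCD reading requires mdtraj and reconstructs frame times from a
  supplied stride; the package's own archive is the canonical format.
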