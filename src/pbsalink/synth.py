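"""Synthetic fixtures with known ground truth.

Every generator is a pure function of its spec and seed.  The central
fixture is a *toy complex*: two roughly spherical atom clusters ("A", the
G-protein analogue, and "B", the GEF analogue) forming a contact
interface, optionally completed by a three-atom nucleotide-like ligand
("LIG", resname GDP, net charge exactly -3 e) at the interface on the A
side and a +2 e divalent ion ("ION", PB radius 1.55 Å).

The *miniature trio* mirrors the three intermediate models of a
G-protein/GEF study in miniature: an ion-free complex, and two
ion-containing variants (canonical vs displaced ion placement) in which
the partner cluster is retracted slightly from the interface — emulating
the looser, smaller-interface complexes observed when the divalent ion
occupies the interfacial site.  The trio is designed so that the ion-free
analogue has the lowest MM-PBSA binding free energy and the largest
buried interface, with the ion's desolvation penalty dominating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import COULOMB_K
from .model_io import Atom, ParameterizedStructure, SnapshotEnsemble
from .titration import TitratableSite

__all__ = [
    "ToySpec",
    "make_toy_complex",
    "make_snapshot_ensemble",
    "make_trio",
    "born_fixture",
    "two_site_titration_fixture",
]

# name, charge (e), lj_epsilon (kcal/mol), lj_rmin_half (Å), pb_radius (Å).
# Atoms are assigned to cluster positions sorted by distance to the
# interface, so the cycle order fixes the interfacial chemistry: the
# G-protein analogue presents a basic (Lys30-like) atom to its nucleotide,
# the partner analogue leads with its basic residues — the arrangement
# seen at real exchange-factor interfaces.
_PROTEIN_ATOM_CYCLE = [
    ("NZ", 0.40, 0.20, 1.85, 1.8),
    ("CA", 0.10, 0.10, 2.0, 2.0),
    ("CB", -0.10, 0.10, 2.0, 2.0),
    ("OD", -0.40, 0.12, 1.7, 1.6),
    ("CG", 0.00, 0.08, 2.05, 2.0),
]
# partner cluster carries a net positive charge (basic-residue analogues)
_PARTNER_ATOM_CYCLE = [
    ("NZ", 0.50, 0.20, 1.85, 1.8),
    ("NH", 0.40, 0.20, 1.85, 1.8),
    ("CA", 0.10, 0.10, 2.0, 2.0),
    ("CB", -0.10, 0.10, 2.0, 2.0),
    ("CG", 0.00, 0.08, 2.05, 2.0),
]
# three-atom nucleotide-like group, net charge -3 e
_LIGAND_ATOMS = [
    ("PB", -1.10, 0.585, 2.15, 2.1),
    ("O2B", -0.95, 0.12, 1.7, 1.6),
    ("O3B", -0.95, 0.12, 1.7, 1.6),
]
_ION = ("MG", 2.0, 0.0135, 1.185, 1.55)

_MIN_SEP = 0.5  # Å, regenerate below this


@dataclass(frozen=True)
class ToySpec:
    """Parameters of the toy two-cluster complex."""

    n_atoms_a: int = 30
    n_atoms_b: int = 30
    ligand: bool = True
    ion: bool = False
    ion_site: str = "canonical"  # or "displaced"
    seed: int = 0
    jitter_sd: float = 0.0
    gap: float = 3.8  # Å between cluster surfaces (near LJ contact distance)
    b_retraction: float = 0.0  # Å extra separation of cluster B


def _cluster(rng, n, center, radius, forbidden=None, forbidden_dist=3.2):
    """n points quasi-uniform in a sphere.

    Pairwise separation >= 0.5 Å within the cluster and >= forbidden_dist
    from any listed forbidden point (ligand/ion sites), so interfacial
    contacts stay near Lennard-Jones contact distance rather than
    clashing.
    """
    pts = []
    attempts = 0
    while len(pts) < n:
        p = center + radius * (rng.random(3) * 2.0 - 1.0)
        if np.linalg.norm(p - center) > radius:
            continue
        bad = pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) < 2.0
        if forbidden is not None and len(forbidden):
            bad = bad or np.min(
                np.linalg.norm(np.asarray(forbidden) - p, axis=1)
            ) < forbidden_dist
        if bad:
            attempts += 1
            if attempts > 500 * n:
                raise RuntimeError("could not place non-overlapping atoms")
            continue
        pts.append(p)
    return np.array(pts)


def make_toy_complex(spec: ToySpec) -> ParameterizedStructure:
    """Build the parameterized toy complex described in the module docstring.

    Groups registered: "A", "B", and when present "LIG" and "ION".
    Deterministic under ``spec.seed``.
    """
    if spec.n_atoms_a < 1 or spec.n_atoms_b < 1:
        raise ValueError("cluster atom counts must be >= 1")
    rng = np.random.default_rng(spec.seed)
    r_a = max(3.0, 1.6 * spec.n_atoms_a ** (1 / 3))
    r_b = max(3.0, 1.6 * spec.n_atoms_b ** (1 / 3))
    sep = r_a + r_b + spec.gap + spec.b_retraction
    center_a = np.zeros(3)
    center_b = np.array([sep, 0.0, 0.0])

    # ligand / ion sites are fixed before the clusters so cluster atoms
    # keep contact (not clash) distance from them
    iface_pt = center_a + np.array([r_a + 0.3 * spec.gap, 0.0, 0.0])
    lig_pts = np.empty((0, 3))
    if spec.ligand:
        lig0 = iface_pt + np.array([-0.8, 1.8, 0.0])
        lig_offsets = [np.zeros(3), np.array([1.5, 0.6, 0.0]),
                       np.array([0.4, -1.4, 0.9])]
        lig_pts = np.array([lig0 + off for off in lig_offsets])
    ion_pt = None
    if spec.ion:
        if spec.ion_site == "canonical":
            ion_pt = iface_pt + np.array([2.2, 1.5, 0.3])
        elif spec.ion_site == "displaced":
            ion_pt = iface_pt + np.array([2.4, -0.9, -1.1])
        else:
            raise ValueError(f"unknown ion_site {spec.ion_site!r}")
    forbidden = lig_pts if ion_pt is None else np.vstack([lig_pts, ion_pt])

    pts_a = _cluster(rng, spec.n_atoms_a, center_a, r_a, forbidden)
    pts_b = _cluster(rng, spec.n_atoms_b, center_b, r_b, forbidden)
    # interface-first ordering: nearest the interface point gets the
    # first cycle entry
    pts_a = pts_a[np.argsort(np.linalg.norm(pts_a - iface_pt, axis=1))]
    pts_b = pts_b[np.argsort(np.linalg.norm(pts_b - iface_pt, axis=1))]

    atoms = []
    groups = {}

    def add(name, q, eps, rmh, pbr, pos, resname, resid, chain):
        atoms.append(
            Atom(
                serial=len(atoms) + 1,
                name=name,
                residue_name=resname,
                residue_id=resid,
                chain_id=chain,
                position=pos,
                charge=q,
                lj_epsilon=eps,
                lj_rmin_half=rmh,
                pb_radius=pbr,
                element=name[:1],
            )
        )
        return len(atoms) - 1

    idx_a = []
    for i, p in enumerate(pts_a):
        name, q, eps, rmh, pbr = _PROTEIN_ATOM_CYCLE[i % len(_PROTEIN_ATOM_CYCLE)]
        idx_a.append(add(name, q, eps, rmh, pbr, p, "GLY", i // 3 + 1, "A"))
    idx_b = []
    for i, p in enumerate(pts_b):
        name, q, eps, rmh, pbr = _PARTNER_ATOM_CYCLE[i % len(_PARTNER_ATOM_CYCLE)]
        idx_b.append(add(name, q, eps, rmh, pbr, p, "GLY", i // 3 + 1, "B"))
    groups["A"] = idx_a
    groups["B"] = idx_b

    if spec.ligand:
        idx_l = []
        for (name, q, eps, rmh, pbr), p in zip(_LIGAND_ATOMS, lig_pts):
            idx_l.append(add(name, q, eps, rmh, pbr, p, "GDP", 500, "L"))
        groups["LIG"] = idx_l
    if spec.ion:
        # both sites sit in the interfacial seam so that partner binding
        # desolvates the ion; the displaced site is deeper into the seam
        name, q, eps, rmh, pbr = _ION
        groups["ION"] = [add(name, q, eps, rmh, pbr, ion_pt, "MG", 600, "M")]

    s = ParameterizedStructure(atoms, groups)
    xyz = s.coords
    d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    if d.min() < _MIN_SEP:
        raise RuntimeError("atom placement produced a clash")
    return s


def make_snapshot_ensemble(
    toy: ParameterizedStructure,
    n_frames: int,
    jitter_sd: float = 0.1,
    rigid_rock_deg: float = 0.0,
    seed: int = 0,
    stride_ps: float = 40.0,
) -> SnapshotEnsemble:
    """Gaussian-jitter snapshot ensemble about the reference coordinates.

    Optionally group "B" rocks rigidly by ±rigid_rock_deg about a z-axis
    hinge through its centroid (alternating sign per frame), providing a
    clean relative-orientation signal on top of the jitter.
    """
    if n_frames < 2:
        raise ValueError("need at least two frames")
    rng = np.random.default_rng(seed)
    ref = toy.coords
    frames = np.empty((n_frames, len(ref), 3))
    b = toy.groups.get("B", np.array([], dtype=int))
    hinge = ref[b].mean(axis=0) if b.size else np.zeros(3)
    for f in range(n_frames):
        frame = ref + rng.normal(0.0, jitter_sd, ref.shape)
        if rigid_rock_deg != 0.0 and b.size:
            theta = np.deg2rad(rigid_rock_deg) * (1.0 if f % 2 == 0 else -1.0)
            c, s_ = np.cos(theta), np.sin(theta)
            R = np.array([[c, -s_, 0.0], [s_, c, 0.0], [0.0, 0.0, 1.0]])
            frame[b] = (frame[b] - hinge) @ R.T + hinge
        frames[f] = frame
    times = stride_ps * np.arange(n_frames)
    return SnapshotEnsemble(toy, frames, times)


def make_trio(seed: int = 0, n_atoms: int = 30):
    """The miniature intermediate trio: ion-free, canonical-ion and
    displaced-ion complexes.  Returns {'IIo': ..., 'IIm1': ..., 'IIm2': ...}.

    The two ion-containing variants place the +2 e ion at the interface
    and retract the partner cluster by 2.5 Å, so that ion desolvation and
    the reduced contact dominate the MM-PBSA comparison — the ion-free
    complex has the lowest binding free energy and the largest interface.
    """
    base = dict(n_atoms_a=n_atoms, n_atoms_b=n_atoms, ligand=True, seed=seed)
    return {
        "IIo": make_toy_complex(ToySpec(ion=False, **base)),
        "IIm1": make_toy_complex(
            ToySpec(ion=True, ion_site="canonical", b_retraction=2.5, **base)
        ),
        "IIm2": make_toy_complex(
            ToySpec(ion=True, ion_site="displaced", b_retraction=2.5, **base)
        ),
    }


def born_fixture(q: float = 1.0, radius: float = 2.0, eps_solvent: float = 80.0):
    """Single-ion structure plus the closed-form Born solvation energy
    -(k q^2 / 2r)(1 - 1/eps_w), kcal/mol."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    atom = Atom(
        serial=1, name="ION", residue_name="ION", residue_id=1, chain_id="I",
        position=np.zeros(3), charge=q, lj_epsilon=0.0, lj_rmin_half=radius,
        pb_radius=radius, element="X",
    )
    structure = ParameterizedStructure([atom], {"ION": [0]})
    analytic = -(COULOMB_K * q * q / (2.0 * radius)) * (1.0 - 1.0 / eps_solvent)
    return structure, analytic


def two_site_titration_fixture(pka1: float, pka2: float, w12: float):
    """Two coupled acid sites with an analytic 4-state oracle.

    Returns (sites, matrix, curve_fn) where curve_fn(ph) evaluates the
    exact mean protonation (site1, site2) by explicit 4-state partition
    function — an oracle independent of the titration machinery.
    """
    from .constants import KT, KT_LN10

    sites = [
        TitratableSite(id="S1", atom_index=0, model_pka=pka1, is_acid=True,
                       intrinsic_pka=pka1),
        TitratableSite(id="S2", atom_index=1, model_pka=pka2, is_acid=True,
                       intrinsic_pka=pka2),
    ]
    matrix = np.array([[0.0, w12], [w12, 0.0]])

    def curve_fn(ph):
        # states (s1, s2); acids: charged when deprotonated
        states = [(0, 0), (0, 1), (1, 0), (1, 1)]
        weights = []
        for s1, s2 in states:
            e = KT_LN10 * (s1 * (ph - pka1) + s2 * (ph - pka2))
            e += w12 * (1 - s1) * (1 - s2)
            weights.append(np.exp(-e / KT))
        z = sum(weights)
        p1 = (weights[2] + weights[3]) / z
        p2 = (weights[1] + weights[3]) / z
        return np.array([p1, p2])

    return sites, matrix, curve_fn
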