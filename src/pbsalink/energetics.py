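"""Group-group molecular-mechanics interaction energies.

Two nonbonded modes are used and never mixed implicitly:

* trajectory interaction energies (interface and ion analyses): Lennard-
  Jones plus *force-shift* Coulomb with a 12 Å cutoff, dielectric 1
  (explicit-solvent convention);
* MM-PBSA end-point energies: Lennard-Jones with **no** cutoff (the
  electrostatics are handled by the continuum solver instead).

The force-shift potential multiplies nothing into LJ; it applies to the
Coulomb term only:  E(r) = k q_i q_j (1/r - 2/r_c + r/r_c^2) for r <= r_c,
0 beyond, so that both the energy and its derivative vanish continuously
at the cutoff.

All analyzed pairs are intergroup (separate molecules/ions), so no 1-4
scaling or bonded exclusions apply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import COULOMB_K
from .model_io import ParameterizedStructure, SnapshotEnsemble

__all__ = [
    "InteractionEnergy",
    "NonbondedSettings",
    "lj_energy",
    "coulomb_force_shift",
    "interaction_energy",
    "interaction_energy_series",
    "per_residue_decomposition",
]

_CLASH_R = 1e-6  # Å


@dataclass
class InteractionEnergy:
    """Electrostatic + van der Waals interaction energy, kcal/mol."""

    elec: float
    vdw: float

    @property
    def total(self) -> float:
        return self.elec + self.vdw


@dataclass
class NonbondedSettings:
    """Cutoff scheme for pairwise nonbonded sums.

    cutoff=None disables the cutoff entirely (MM-PBSA vdW mode); otherwise
    the Coulomb term uses the shifted-force form and the LJ term is
    truncated at the cutoff.
    """

    cutoff: float | None = 12.0
    coulomb_constant: float = COULOMB_K

    def __post_init__(self) -> None:
        if self.cutoff is not None and self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


def _pair_arrays(structure: ParameterizedStructure, group_a, group_b, coords):
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty atom group")
    if np.intersect1d(a, b).size:
        raise ValueError("groups overlap; interaction energy requires disjoint groups")
    coords = structure.coords if coords is None else np.asarray(coords, dtype=float)
    r = np.linalg.norm(coords[a][:, None, :] - coords[b][None, :, :], axis=2)
    if np.any(r < _CLASH_R):
        raise ValueError("atom clash: interatomic distance below 1e-6 Å")
    return a, b, r


def lj_energy(
    structure: ParameterizedStructure,
    group_a,
    group_b,
    coords=None,
    settings: NonbondedSettings | None = None,
) -> float:
    """Lennard-Jones interaction between two disjoint groups, kcal/mol.

    CHARMM combining rules: eps_ij = sqrt(eps_i eps_j),
    rmin_ij = rmin_half_i + rmin_half_j;
    E = sum eps_ij [ (rmin_ij/r)^12 - 2 (rmin_ij/r)^6 ].
    A cutoff (plain truncation) is applied only when settings carry one.
    """
    settings = settings or NonbondedSettings(cutoff=None)
    a, b, r = _pair_arrays(structure, group_a, group_b, coords)
    eps = np.array([at.lj_epsilon for at in structure.atoms])
    rmh = np.array([at.lj_rmin_half for at in structure.atoms])
    if np.any(~np.isfinite(eps[a])) or np.any(~np.isfinite(eps[b])):
        raise ValueError("LJ parameters unset for some atoms")
    eps_ij = np.sqrt(eps[a][:, None] * eps[b][None, :])
    rmin_ij = rmh[a][:, None] + rmh[b][None, :]
    s6 = (rmin_ij / r) ** 6
    e = eps_ij * (s6 * s6 - 2.0 * s6)
    if settings.cutoff is not None:
        e = np.where(r <= settings.cutoff, e, 0.0)
    return float(e.sum())


def coulomb_force_shift(
    structure: ParameterizedStructure,
    group_a,
    group_b,
    coords=None,
    settings: NonbondedSettings | None = None,
) -> float:
    """Force-shift Coulomb interaction between disjoint groups, kcal/mol.

    With cutoff r_c:  E = k q_i q_j (1/r - 2/r_c + r/r_c^2), zero beyond
    r_c.  With cutoff=None the bare Coulomb sum k q_i q_j / r is returned.
    """
    settings = settings or NonbondedSettings()
    a, b, r = _pair_arrays(structure, group_a, group_b, coords)
    q = structure.charges
    if np.any(~np.isfinite(q[a])) or np.any(~np.isfinite(q[b])):
        raise ValueError("charges unset for some atoms")
    qq = q[a][:, None] * q[b][None, :]
    k = settings.coulomb_constant
    if settings.cutoff is None:
        e = k * qq / r
    else:
        rc = settings.cutoff
        e = np.where(r <= rc, k * qq * (1.0 / r - 2.0 / rc + r / rc**2), 0.0)
    return float(e.sum())


def interaction_energy(
    structure: ParameterizedStructure,
    group_a,
    group_b,
    coords=None,
    settings: NonbondedSettings | None = None,
) -> InteractionEnergy:
    """Combined elec + vdW group-group interaction for one frame."""
    settings = settings or NonbondedSettings()
    return InteractionEnergy(
        elec=coulomb_force_shift(structure, group_a, group_b, coords, settings),
        vdw=lj_energy(structure, group_a, group_b, coords, settings),
    )


def interaction_energy_series(
    ensemble: SnapshotEnsemble,
    group_a,
    group_b,
    settings: NonbondedSettings | None = None,
) -> list[InteractionEnergy]:
    """Per-frame group-group interaction energies along an ensemble."""
    if ensemble.n_frames == 0:
        raise ValueError("empty ensemble")
    settings = settings or NonbondedSettings()
    return [
        interaction_energy(ensemble.topology, group_a, group_b, frame, settings)
        for frame in ensemble.frames
    ]


def per_residue_decomposition(
    structure: ParameterizedStructure,
    probe_group,
    partner,
    coords=None,
    settings: NonbondedSettings | None = None,
) -> dict:
    """Decompose probe-partner interaction over the partner's residues.

    Returns {(chain_id, residue_id, residue_name): InteractionEnergy}.
    By pairwise additivity the entries sum to the full group-group energy.
    Used e.g. to quantify how much a single GEF residue contributes to the
    interaction with the divalent ion.
    """
    settings = settings or NonbondedSettings()
    partner = np.asarray(partner, dtype=int)
    keys = {}
    for i in partner:
        a = structure.atoms[i]
        keys.setdefault((a.chain_id, a.residue_id, a.residue_name), []).append(i)
    out = {}
    for key, idx in keys.items():
        out[key] = interaction_energy(structure, probe_group, idx, coords, settings)
    return out
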