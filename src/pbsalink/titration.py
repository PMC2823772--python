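"""Multi-site pKa titration from continuum electrostatics.

The workflow follows the classical FDPB pKa recipe: each ionizable site
gets (i) a *model* pKa — its value in a model compound free in water;
(ii) an *intrinsic* pKa — the model value shifted by the FDPB work of
charging the site inside the protein (desolvation plus interaction with
non-titrating background charges) while every other site is held neutral;
and (iii) pairwise charged-charged site couplings W_ij.  Titration curves
then come from a Boltzmann average over ionization microstates, either by
exact 2^n enumeration (n <= 20) or Metropolis Monte Carlo.

The site model is deliberately simple: the charged and neutral forms of a
site differ by exactly +-1 e placed on the titratable atom (acids lose,
bases gain a proton charge).  The standard amino-acid sites are built in,
and a nucleotide beta-phosphate oxygen (model pKa 6.4 in water) can be
added to handle the additional ionization centre of a bound GDP.

Microstate energy (s_i = 1 when protonated; z_i = 1 when charged):

    E(s; pH) = sum_i s_i * ln(10) kT (pH - pKa_intr,i)
             + sum_{i<j} W_ij z_i z_j
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KT, KT_LN10
from .model_io import ParameterizedStructure
from . import pb

__all__ = [
    "TitratableSite",
    "TitrationResult",
    "STANDARD_SITE_TABLE",
    "define_sites",
    "intrinsic_pka",
    "site_interaction_matrix",
    "titrate",
    "henderson_hasselbalch",
    "pka_half_from_curve",
    "verify_ionization_states",
]

#: residue -> (titratable atom, model pKa, is_acid). Model pKa values are
#: the usual aqueous model-compound values; charged form differs from the
#: neutral form by -1 e (acid) or +1 e (base) on the listed atom.
STANDARD_SITE_TABLE = {
    "ASP": ("OD2", 4.0, True),
    "GLU": ("OE2", 4.4, True),
    "HIS": ("NE2", 6.3, False),
    "LYS": ("NZ", 10.4, False),
    "ARG": ("CZ", 12.0, False),
    "TYR": ("OH", 9.6, True),
    "CYS": ("SG", 8.3, True),
}

#: aqueous model pKa of the extra phosphate ionization centre (GDP O2B).
PHOSPHATE_O2B_MODEL_PKA = 6.4


@dataclass
class TitratableSite:
    """One ionizable group reduced to a single titratable atom."""

    id: str
    atom_index: int
    model_pka: float
    is_acid: bool
    intrinsic_pka: float | None = None

    @property
    def delta_charge(self) -> float:
        """Charge difference charged - neutral on the titratable atom, e."""
        return -1.0 if self.is_acid else +1.0

    @property
    def pka(self) -> float:
        """Intrinsic pKa when computed, otherwise the model pKa."""
        return self.model_pka if self.intrinsic_pka is None else self.intrinsic_pka


@dataclass
class TitrationResult:
    """Mean protonation per site over a pH grid, and pKa-half values."""

    ph_grid: np.ndarray
    mean_protonation: np.ndarray  # (n_ph, n_sites), in [0, 1]
    pka_half: np.ndarray  # per site
    site_ids: list
    method: str
    mc_seed: int | None = None
    diagnostics: dict = field(default_factory=dict)


def define_sites(
    structure: ParameterizedStructure,
    site_table: dict | None = None,
    include_phosphate_o2b: bool = False,
) -> list:
    """Scan a structure for ionizable residues and build the site list.

    A residue listed in the table whose titratable atom is absent raises
    an error naming the site.  With ``include_phosphate_o2b`` the GDP O2B
    oxygen is added at model pKa 6.4.
    """
    table = STANDARD_SITE_TABLE if site_table is None else site_table
    residues = {}
    for i, a in enumerate(structure.atoms):
        residues.setdefault((a.chain_id, a.residue_id, a.residue_name), {})[a.name] = i

    sites = []
    for (chain, resid, resname), atom_map in residues.items():
        if resname in table:
            atom_name, pka, is_acid = table[resname]
            if atom_name not in atom_map:
                raise ValueError(
                    f"site {resname}{resid}:{chain}: titratable atom "
                    f"{atom_name!r} missing from structure"
                )
            sites.append(
                TitratableSite(
                    id=f"{resname}{resid}:{chain}",
                    atom_index=atom_map[atom_name],
                    model_pka=pka,
                    is_acid=is_acid,
                )
            )
        if include_phosphate_o2b and resname == "GDP":
            if "O2B" not in atom_map:
                raise ValueError(
                    f"site GDP{resid}:{chain}: atom 'O2B' missing from structure"
                )
            sites.append(
                TitratableSite(
                    id=f"GDP{resid}:{chain}/O2B",
                    atom_index=atom_map["O2B"],
                    model_pka=PHOSPHATE_O2B_MODEL_PKA,
                    is_acid=True,
                )
            )
    return sites


def _model_compound_region(site, structure):
    """Atoms of the site's own residue — the model compound in water."""
    a0 = structure.atoms[site.atom_index]
    return np.array(
        [i for i, a in enumerate(structure.atoms)
         if (a.chain_id, a.residue_id) == (a0.chain_id, a0.residue_id)]
    )


def _site_potential(site, structure, specs, eps_protein, eps_solvent,
                    ionic_strength_mM, stern, tol, model_compound=False):
    """Solve the FDPB ladder for a unit site charge; returns (phi, maps).

    Geometry comes from the whole structure (or only the site's residue
    when ``model_compound``); the source charge is the site's +-1 e delta
    on its titratable atom.
    """
    if model_compound:
        region = _model_compound_region(site, structure)
    else:
        region = np.arange(len(structure))
    charges = np.zeros(len(structure))
    charges[site.atom_index] = site.delta_charge
    probe = _override_charges(structure, charges)
    return pb.solve_ladder(probe, region, specs, eps_protein, eps_solvent,
                           ionic_strength_mM, stern, tol)


def _override_charges(structure, charges):
    from dataclasses import replace

    atoms = [replace(a, charge=float(q)) for a, q in zip(structure.atoms, charges)]
    return ParameterizedStructure(atoms, dict(structure.groups))


def intrinsic_pka(
    site: TitratableSite,
    structure: ParameterizedStructure,
    specs,
    eps_protein: float = 20.0,
    eps_solvent: float = 80.0,
    ionic_strength_mM: float = 150.0,
    stern: float = 2.0,
    tol: float = 1e-6,
    background_charges=None,
) -> float:
    """Intrinsic pKa of a site with all other sites neutral.

    The charging work of the site's +-1 e delta is compared between the
    full protein environment and the model compound (the site's own
    residue) in water:

    ddG = [W_Born(protein) - W_Born(model)]
        + [sum_{protein bg} q phi_protein(x) - sum_{model bg} q phi_model(x)]

    evaluated on identical focusing ladders so the grid self-energy
    cancels between the two environments, and with the model compound's
    own background charges subtracted (they act on the site in both
    states).  For an acid a positive ddG (charging penalized in the
    protein) raises the pKa; for a base it lowers it.
    ``background_charges`` defaults to the structure's charges (the
    structure is expected to carry neutral-form charges for the other
    titratable sites); the site's own atom is always zeroed.
    """
    phi_p, maps_p = _site_potential(site, structure, specs, eps_protein,
                                    eps_solvent, ionic_strength_mM, stern, tol)
    phi_m, maps_m = _site_potential(site, structure, specs, eps_protein,
                                    eps_solvent, ionic_strength_mM, stern, tol,
                                    model_compound=True)
    w_born = pb.charging_energy(phi_p, maps_p) - pb.charging_energy(phi_m, maps_m)

    q_bg = structure.charges.copy() if background_charges is None else np.asarray(
        background_charges, float).copy()
    q_bg[site.atom_index] = 0.0
    q_bg = np.nan_to_num(q_bg)
    xyz = structure.coords

    def bg_term(phi, indices):
        interp = phi.interpolator()
        lo = phi.spec.origin
        hi = lo + phi.spec.length
        sel = np.zeros(len(xyz), dtype=bool)
        sel[indices] = True
        sel &= np.all((xyz >= lo) & (xyz <= hi), axis=1) & (q_bg != 0)
        if not np.any(sel):
            return 0.0
        return float(np.sum(q_bg[sel] * interp(xyz[sel])))

    model_region = _model_compound_region(site, structure)
    w_bg = bg_term(phi_p, np.arange(len(xyz))) - bg_term(phi_m, model_region)

    ddg = w_born + w_bg
    shift = ddg / KT_LN10
    pka = site.model_pka + shift if site.is_acid else site.model_pka - shift
    site.intrinsic_pka = float(pka)
    return float(pka)


def site_interaction_matrix(
    sites,
    structure: ParameterizedStructure,
    specs,
    eps_protein: float = 20.0,
    eps_solvent: float = 80.0,
    ionic_strength_mM: float = 150.0,
    stern: float = 2.0,
    tol: float = 1e-6,
) -> np.ndarray:
    """Pairwise charged-charged FDPB interaction energies W_ij, kcal/mol.

    W_ij = dq_j * phi_i(x_j) with phi_i the potential of site i's unit
    delta charge in the full protein environment (others neutral).  The
    matrix is symmetrized (it is symmetric within solver tolerance);
    diagonal zero.
    """
    if len(sites) < 2:
        raise ValueError("need at least two sites")
    n = len(sites)
    W = np.zeros((n, n))
    xyz = structure.coords
    for i, si in enumerate(sites):
        phi_i, _ = _site_potential(si, structure, specs, eps_protein,
                                   eps_solvent, ionic_strength_mM, stern, tol)
        interp = phi_i.interpolator()
        for j, sj in enumerate(sites):
            if i == j:
                continue
            W[i, j] = sj.delta_charge * float(interp(xyz[sj.atom_index][None])[0])
    return 0.5 * (W + W.T)


def henderson_hasselbalch(ph, pka) -> np.ndarray:
    """Mean protonation of an isolated site: 1 / (1 + 10^(pH - pKa))."""
    return 1.0 / (1.0 + 10.0 ** (np.asarray(ph, float) - pka))


def _microstate_energies(sites, matrix, states, ph):
    """Energies (kcal/mol) of protonation microstates at one pH."""
    pka = np.array([s.pka for s in sites])
    acid = np.array([s.is_acid for s in sites])
    z = np.where(acid[None, :], 1 - states, states)  # charged indicators
    e_ph = KT_LN10 * states @ (ph - pka)
    e_pair = 0.5 * np.einsum("si,ij,sj->s", z, matrix, z)
    return e_ph + e_pair


def _exact_mean_protonation(sites, matrix, ph):
    n = len(sites)
    states = ((np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1).astype(float)
    e = _microstate_energies(sites, matrix, states, ph)
    w = np.exp(-(e - e.min()) / KT)
    w /= w.sum()
    return w @ states


def _mc_mean_protonation(sites, matrix, ph, rng, n_equil, n_sweeps):
    n = len(sites)
    pka = np.array([s.pka for s in sites])
    acid = np.array([s.is_acid for s in sites])
    s = (rng.random(n) < 0.5).astype(float)
    acc = np.zeros(n)
    total = np.zeros(n)
    for sweep in range(n_equil + n_sweeps):
        for i in rng.permutation(n):
            s_new = 1.0 - s[i]
            d_ph = KT_LN10 * (s_new - s[i]) * (ph - pka[i])
            z = np.where(acid, 1 - s, s)
            z_i_old = z[i]
            z_i_new = (1 - s_new) if acid[i] else s_new
            zz = z.copy()
            zz[i] = 0.0
            d_pair = (z_i_new - z_i_old) * float(matrix[i] @ zz)
            dE = d_ph + d_pair
            if dE <= 0 or rng.random() < np.exp(-dE / KT):
                s[i] = s_new
                acc[i] += 1
        if sweep >= n_equil:
            total += s
    return total / n_sweeps, acc / (n_equil + n_sweeps)


def pka_half_from_curve(ph_grid, curve) -> float:
    """pH at which mean protonation crosses 0.5 (linear interpolation /
    bisection of the sampled curve); NaN if it never crosses."""
    curve = np.asarray(curve, float)
    ph_grid = np.asarray(ph_grid, float)
    above = curve >= 0.5
    if above.all() or (~above).all():
        return float("nan")
    k = int(np.nonzero(above[:-1] & ~above[1:])[0][0])
    p0, p1 = ph_grid[k], ph_grid[k + 1]
    c0, c1 = curve[k], curve[k + 1]
    return float(p0 + (0.5 - c0) * (p1 - p0) / (c1 - c0))


def titrate(
    sites,
    matrix=None,
    ph_range=(0.0, 14.0),
    n_ph: int = 57,
    method: str = "exact",
    seed: int | None = None,
    n_equil_sweeps: int = 1000,
    n_sweeps: int = 10_000,
) -> TitrationResult:
    """Boltzmann-average protonation over ionization microstates.

    ``method='exact'`` enumerates all 2^n microstates (n <= 20);
    ``'monte-carlo'`` runs seeded Metropolis single-site flips.  The
    pKa-half of each site is the pH at which its mean protonation curve
    crosses one half.
    """
    n = len(sites)
    if n == 0:
        raise ValueError("no sites")
    matrix = np.zeros((n, n)) if matrix is None else np.asarray(matrix, float)
    if matrix.shape != (n, n):
        raise ValueError("coupling matrix shape mismatch")
    ph_grid = np.linspace(ph_range[0], ph_range[1], n_ph)

    if method == "exact":
        if n > 20:
            raise ValueError(
                f"exact enumeration limited to 20 sites (got {n}); "
                "use method='monte-carlo'"
            )
        mean_prot = np.array([_exact_mean_protonation(sites, matrix, ph)
                              for ph in ph_grid])
        diagnostics = {}
        mc_seed = None
        # exact curves admit true bisection roots for pKa-half
        from scipy.optimize import brentq

        pka_half = []
        for j in range(n):
            f = lambda ph: _exact_mean_protonation(sites, matrix, ph)[j] - 0.5
            lo, hi = ph_range
            if f(lo) < 0 or f(hi) > 0:
                pka_half.append(float("nan"))
            else:
                pka_half.append(float(brentq(f, lo, hi, xtol=1e-10)))
        return TitrationResult(
            ph_grid=ph_grid,
            mean_protonation=mean_prot,
            pka_half=np.array(pka_half),
            site_ids=[s.id for s in sites],
            method=method,
        )
    elif method == "monte-carlo":
        if seed is None:
            raise ValueError("monte-carlo titration requires a seed")
        rng = np.random.default_rng(seed)
        rows, acc = [], []
        for ph in ph_grid:
            mp, a = _mc_mean_protonation(sites, matrix, ph, rng,
                                         n_equil_sweeps, n_sweeps)
            rows.append(mp)
            acc.append(a)
        mean_prot = np.array(rows)
        diagnostics = {"acceptance_rate": float(np.mean(acc))}
        mc_seed = seed
    else:
        raise ValueError(f"unknown titration method {method!r}")

    pka_half = np.array([pka_half_from_curve(ph_grid, mean_prot[:, j])
                         for j in range(n)])
    return TitrationResult(
        ph_grid=ph_grid,
        mean_protonation=mean_prot,
        pka_half=pka_half,
        site_ids=[s.id for s in sites],
        method=method,
        mc_seed=mc_seed,
        diagnostics=diagnostics,
    )


def verify_ionization_states(sites, result: TitrationResult, ph: float = 7.0) -> list:
    """Compare each site's most probable state at the given pH with its
    standard assignment (acids deprotonated / bases protonated when the
    model pKa is on the appropriate side of the pH).

    Returns a list of dicts; entry['flagged'] marks sites whose computed
    most-probable state deviates from the standard one.
    """
    k = int(np.argmin(np.abs(result.ph_grid - ph)))
    report = []
    for j, site in enumerate(sites):
        prot = result.mean_protonation[k, j]
        protonated = prot >= 0.5
        standard_protonated = site.model_pka > ph
        charged = (not protonated) if site.is_acid else protonated
        report.append(
            {
                "site": site.id,
                "mean_protonation": float(prot),
                "most_probable_protonated": bool(protonated),
                "charged": bool(charged),
                "pka_half": float(result.pka_half[j]),
                "flagged": bool(protonated != standard_protonated),
            }
        )
    return report
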