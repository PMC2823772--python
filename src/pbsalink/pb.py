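"""Finite-difference linearized Poisson-Boltzmann (FDPB) solver.

The electrostatic potential phi (kcal/(mol·e)) on a cubic grid satisfies
the linearized PB equation

    div( eps grad phi ) - kbar2 phi = -4 pi k_c rho

with eps the position-dependent dielectric, rho the source charge density
(e/Å³) and kbar2 = eps_w * kappa^2 the modified screening factor, zero
inside the solute and its Stern (ion-exclusion) layer.  kappa is the
inverse Debye length of the bulk salt at 300 K.

Discretization: standard 7-point stencil on a uniform cubic grid with
*harmonic-mean* dielectrics on cell faces (a smoothed dielectric
boundary), trilinear spreading of atomic charges to the eight surrounding
nodes, and Dirichlet boundary values from a screened-Coulomb (single
Debye-Hückel monopole per atom) sum.  The resulting symmetric
positive-definite system is solved by preconditioned conjugate gradients.

*Focusing* re-solves on successively finer sub-grids whose boundary
values are interpolated from the coarser solution, giving fine spacing
near the region of interest at the cost of coarse far-field resolution.

Charging free energies W = 1/2 sum_i q_i phi(x_i) contain a grid
self-energy that depends on the spreading; it cancels exactly when two
environments (e.g. eps_out = eps_w vs eps_out = eps_p) are differenced on
the identical grid, which is how all solvation quantities here are
defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import RegularGridInterpolator
from scipy.sparse.linalg import cg

from .constants import COULOMB_K, KT, MOLAR_TO_PER_A3
from .model_io import ParameterizedStructure

__all__ = [
    "GridSpec",
    "DielectricMaps",
    "PotentialGrid",
    "kappa2_bar",
    "build_maps",
    "solve_lpbe",
    "focus",
    "charging_energy",
    "solve_ladder",
    "charging_energy_ladder",
    "elec_solvation_binding",
    "reaction_field_energy",
    "potential_difference_map",
    "write_dx",
]

FOUR_PI_K = 4.0 * np.pi * COULOMB_K


@dataclass(frozen=True)
class GridSpec:
    """Cubic grid: ``n`` nodes per edge, uniform ``spacing`` Å, centered."""

    center: tuple
    n: int
    spacing: float

    def __post_init__(self):
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.n < 5:
            raise ValueError("grid needs at least 5 nodes per edge")

    @property
    def length(self) -> float:
        return (self.n - 1) * self.spacing

    @property
    def origin(self) -> np.ndarray:
        return np.asarray(self.center, float) - 0.5 * self.length

    def axes(self):
        o = self.origin
        ax = [o[d] + self.spacing * np.arange(self.n) for d in range(3)]
        return ax

    def contains(self, other: "GridSpec") -> bool:
        """True if the other grid's volume lies strictly inside this one."""
        so, oo = self.origin, other.origin
        return bool(
            np.all(oo > so - 1e-9)
            and np.all(oo + other.length < so + self.length + 1e-9)
            and other.length < self.length
        )


@dataclass
class DielectricMaps:
    """Face dielectrics, screening map and distributed source charges."""

    spec: GridSpec
    eps_faces: tuple  # (ex, ey, ez) harmonic-mean face dielectrics
    kappa2: np.ndarray  # modified screening, Å^-2 scale, node-centered
    charge_grid: np.ndarray  # e per node
    eps_protein: float
    eps_solvent: float
    source_positions: np.ndarray = field(default=None)
    source_charges: np.ndarray = field(default=None)
    n_clipped: int = 0  # source charges outside the grid (focused windows)


@dataclass
class PotentialGrid:
    """Scalar potential (kcal/(mol·e)) on a cubic grid."""

    values: np.ndarray
    spec: GridSpec

    def interpolator(self):
        return RegularGridInterpolator(self.spec.axes(), self.values)


def kappa2_bar(ionic_strength_mM: float) -> float:
    """Modified screening factor eps_w * kappa^2 (Å⁻²·eps units).

    kbar2 = 8 pi k_c I / kT with I the ionic strength in Å⁻³; notably
    independent of the solvent dielectric (which cancels against the
    Bjerrum length).
    """
    i_n = ionic_strength_mM * 1e-3 * MOLAR_TO_PER_A3
    return 8.0 * np.pi * COULOMB_K * i_n / KT


def _harmonic(a, b):
    return 2.0 * a * b / (a + b)


def build_maps(
    structure: ParameterizedStructure,
    region,
    spec: GridSpec,
    eps_protein: float = 1.0,
    eps_solvent: float = 80.0,
    ionic_strength_mM: float = 150.0,
    stern: float = 2.0,
    clip_outside: bool = False,
) -> DielectricMaps:
    """Build dielectric/screening/charge maps for a set of atoms.

    ``region`` selects the atoms defining the solute (indices into the
    structure).  Nodes inside any atom sphere (pb_radius) get the protein
    dielectric; faces crossing the boundary get the harmonic mean.  The
    screening map is zeroed within pb_radius + stern of any atom.  Atom
    charges are spread to the 8 surrounding nodes by trilinear weights
    (total charge conserved to 1e-9 e).

    A source charge outside the grid is an error unless ``clip_outside``
    is set — the focused-window case, where charges beyond the window
    contribute only through the boundary values interpolated from the
    parent grid.
    """
    region = np.asarray(region, dtype=int)
    if region.size == 0:
        raise ValueError("empty region")
    pos = structure.coords[region]
    q = structure.charges[region]
    radii = structure.pb_radii[region]
    if np.any(~np.isfinite(q)) or np.any(~np.isfinite(radii)):
        raise ValueError("region atoms must have charge and pb_radius assigned")
    n, h = spec.n, spec.spacing
    origin = spec.origin
    if h > radii[radii > 0].min(initial=np.inf):
        import warnings

        warnings.warn("grid spacing exceeds smallest atomic radius", stacklevel=2)

    ax = spec.axes()
    X = ax[0][:, None, None]
    Y = ax[1][None, :, None]
    Z = ax[2][None, None, :]

    inside = np.zeros((n, n, n), dtype=bool)
    excl = np.zeros((n, n, n), dtype=bool)
    for p, r in zip(pos, radii):
        d2 = (X - p[0]) ** 2 + (Y - p[1]) ** 2 + (Z - p[2]) ** 2
        if r > 0:
            inside |= d2 <= r * r
        rs = r + stern
        excl |= d2 <= rs * rs

    eps_node = np.where(inside, eps_protein, eps_solvent)
    ex = _harmonic(eps_node[:-1], eps_node[1:])
    ey = _harmonic(eps_node[:, :-1], eps_node[:, 1:])
    ez = _harmonic(eps_node[:, :, :-1], eps_node[:, :, 1:])

    k2 = np.where(excl, 0.0, kappa2_bar(ionic_strength_mM))

    charge = np.zeros((n, n, n))
    fi = (pos - origin) / h
    in_grid = np.all((fi >= 0) & (fi <= n - 1), axis=1)
    if not clip_outside and not np.all(in_grid):
        raise ValueError("source charge outside grid")
    q_spread, fi_in = q[in_grid], fi[in_grid]
    base = np.floor(fi_in).astype(int)
    base = np.minimum(base, n - 2)
    frac = fi_in - base
    for a in range(len(q_spread)):
        i, j, k = base[a]
        fx, fy, fz = frac[a]
        for di, wx in ((0, 1 - fx), (1, fx)):
            for dj, wy in ((0, 1 - fy), (1, fy)):
                for dk, wz in ((0, 1 - fz), (1, fz)):
                    charge[i + di, j + dj, k + dk] += q_spread[a] * wx * wy * wz
    assert abs(charge.sum() - q_spread.sum()) < 1e-9

    return DielectricMaps(
        spec=spec,
        eps_faces=(ex, ey, ez),
        kappa2=k2,
        charge_grid=charge,
        eps_protein=eps_protein,
        eps_solvent=eps_solvent,
        source_positions=pos.copy(),
        source_charges=q.copy(),
        n_clipped=int(np.sum(~in_grid)),
    )


def _dh_boundary(maps: DielectricMaps) -> np.ndarray:
    """Screened-Coulomb monopole sum on the 6 grid faces; interior zero."""
    spec = maps.spec
    n = spec.n
    ax = spec.axes()
    phi = np.zeros((n, n, n))
    mask = np.zeros((n, n, n), dtype=bool)
    mask[0], mask[-1] = True, True
    mask[:, 0], mask[:, -1] = True, True
    mask[:, :, 0], mask[:, :, -1] = True, True
    idx = np.argwhere(mask)
    pts = np.column_stack([ax[0][idx[:, 0]], ax[1][idx[:, 1]], ax[2][idx[:, 2]]])
    eps_w = maps.eps_solvent
    k2b = maps.kappa2.max()
    kappa = np.sqrt(k2b / eps_w) if k2b > 0 else 0.0
    vals = np.zeros(len(pts))
    for p, q in zip(maps.source_positions, maps.source_charges):
        r = np.linalg.norm(pts - p, axis=1)
        r = np.maximum(r, 1e-6)
        vals += COULOMB_K * q * np.exp(-kappa * r) / (eps_w * r)
    phi[mask] = vals
    return phi


def solve_lpbe(
    maps: DielectricMaps,
    boundary="debye-huckel-sum",
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> PotentialGrid:
    """Solve the 7-point FD linearized PB equation to the given tolerance.

    ``boundary`` is 'debye-huckel-sum', 'zero', or a full (n,n,n) array of
    which only the face values are used (the focusing path).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    spec = maps.spec
    n, h = spec.n, spec.spacing
    if isinstance(boundary, str):
        if boundary == "zero":
            phi_b = np.zeros((n, n, n))
        elif boundary == "debye-huckel-sum":
            phi_b = _dh_boundary(maps)
        else:
            raise ValueError(f"unknown boundary {boundary!r}")
    else:
        phi_b = np.asarray(boundary, dtype=float)
        if phi_b.shape != (n, n, n):
            raise ValueError("boundary array shape mismatch")

    ex, ey, ez = maps.eps_faces
    m = n - 2
    inv_h2 = 1.0 / (h * h)

    def lin(i, j, k):  # interior (1..n-2) -> flat index
        return ((i - 1) * m + (j - 1)) * m + (k - 1)

    I, J, K = np.meshgrid(
        np.arange(1, n - 1), np.arange(1, n - 1), np.arange(1, n - 1), indexing="ij"
    )
    rows_c = lin(I, J, K).ravel()

    diag = (
        ex[I - 1, J, K] + ex[I, J, K]
        + ey[I, J - 1, K] + ey[I, J, K]
        + ez[I, J, K - 1] + ez[I, J, K]
    ) * inv_h2 + maps.kappa2[I, J, K]
    b = FOUR_PI_K * maps.charge_grid[I, J, K] / h**3

    rows, cols, vals = [rows_c], [rows_c], [diag.ravel()]
    b = b.copy()

    neighbours = [
        (I - 1, J, K, ex[I - 1, J, K]),
        (I + 1, J, K, ex[I, J, K]),
        (I, J - 1, K, ey[I, J - 1, K]),
        (I, J + 1, K, ey[I, J, K]),
        (I, J, K - 1, ez[I, J, K - 1]),
        (I, J, K + 1, ez[I, J, K]),
    ]
    for ni, nj, nk, ef in neighbours:
        interior = (
            (ni >= 1) & (ni <= n - 2)
            & (nj >= 1) & (nj <= n - 2)
            & (nk >= 1) & (nk <= n - 2)
        )
        w = ef * inv_h2
        sel = interior.ravel()
        rows.append(rows_c[sel])
        cols.append(lin(ni, nj, nk).ravel()[sel])
        vals.append(-w.ravel()[sel])
        bsel = ~interior
        if np.any(bsel):
            b[bsel] += w[bsel] * phi_b[ni[bsel], nj[bsel], nk[bsel]]

    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(m**3, m**3),
    )
    b_flat = b.ravel()

    M = sp.diags(1.0 / A.diagonal())
    x, info = cg(A, b_flat, rtol=tol, atol=0.0, maxiter=max_iter, M=M)
    if info != 0:
        resid = np.linalg.norm(A @ x - b_flat) / max(np.linalg.norm(b_flat), 1e-300)
        raise RuntimeError(
            f"PB solver did not converge in {max_iter} iterations "
            f"(relative residual {resid:.3e})"
        )
    phi = phi_b.copy()
    phi[1:-1, 1:-1, 1:-1] = x.reshape(m, m, m)
    return PotentialGrid(values=phi, spec=spec)


def focus(parent: PotentialGrid, maps_child: DielectricMaps, tol: float = 1e-6) -> PotentialGrid:
    """Re-solve on a finer child grid with boundary values from the parent."""
    if not parent.spec.contains(maps_child.spec) and parent.spec != maps_child.spec:
        raise ValueError("child grid must lie inside the parent grid")
    interp = parent.interpolator()
    spec = maps_child.spec
    n = spec.n
    ax = spec.axes()
    phi_b = np.zeros((n, n, n))
    mask = np.zeros((n, n, n), dtype=bool)
    mask[0], mask[-1] = True, True
    mask[:, 0], mask[:, -1] = True, True
    mask[:, :, 0], mask[:, :, -1] = True, True
    idx = np.argwhere(mask)
    pts = np.column_stack([ax[0][idx[:, 0]], ax[1][idx[:, 1]], ax[2][idx[:, 2]]])
    phi_b[mask] = interp(pts)
    return solve_lpbe(maps_child, boundary=phi_b, tol=tol)


def charging_energy(potential: PotentialGrid, maps: DielectricMaps) -> float:
    """W = 1/2 sum_nodes q_node phi_node, kcal/mol (includes grid
    self-energy; difference two identical-grid solves to cancel it)."""
    if potential.spec != maps.spec:
        raise ValueError("potential and maps are on different grids")
    if maps.n_clipped:
        raise ValueError(
            f"{maps.n_clipped} source charges fell outside this grid; "
            "charging energies need a grid enclosing all sources"
        )
    return 0.5 * float(np.sum(maps.charge_grid * potential.values))


def solve_ladder(
    structure: ParameterizedStructure,
    region,
    specs,
    eps_protein: float = 1.0,
    eps_solvent: float = 80.0,
    ionic_strength_mM: float = 150.0,
    stern: float = 2.0,
    tol: float = 1e-6,
):
    """Focusing ladder: solve on specs[0] (Debye-Hückel boundary), focus
    through the remaining specs.  Returns (PotentialGrid, DielectricMaps)
    on the finest grid."""
    maps = build_maps(structure, region, specs[0], eps_protein, eps_solvent,
                      ionic_strength_mM, stern)
    phi = solve_lpbe(maps, "debye-huckel-sum", tol=tol)
    for spec in specs[1:]:
        maps = build_maps(structure, region, spec, eps_protein, eps_solvent,
                          ionic_strength_mM, stern, clip_outside=True)
        phi = focus(phi, maps, tol=tol)
    return phi, maps


def charging_energy_ladder(structure, region, specs, eps_protein, eps_solvent,
                           ionic_strength_mM=150.0, stern=2.0, tol=1e-6) -> float:
    phi, maps = solve_ladder(structure, region, specs, eps_protein, eps_solvent,
                             ionic_strength_mM, stern, tol)
    return charging_energy(phi, maps)


def reaction_field_energy(
    structure: ParameterizedStructure,
    region,
    specs,
    eps_protein: float = 1.0,
    eps_solvent: float = 80.0,
    ionic_strength_mM: float = 150.0,
    stern: float = 2.0,
    tol: float = 1e-6,
) -> float:
    """Electrostatic solvation (reaction-field) energy of one species:
    W(eps_out = eps_solvent, salt) - W(eps_out = eps_protein, no salt) on
    identical grids, so the grid self-energy cancels."""
    w_solv = charging_energy_ladder(structure, region, specs, eps_protein,
                                    eps_solvent, ionic_strength_mM, stern, tol)
    w_ref = charging_energy_ladder(structure, region, specs, eps_protein,
                                   eps_protein, 0.0, stern, tol)
    return w_solv - w_ref


def _coulomb_between(structure, group_a, group_b, eps: float) -> float:
    xyz = structure.coords
    q = structure.charges
    a = np.asarray(group_a, int)
    b = np.asarray(group_b, int)
    r = np.linalg.norm(xyz[a][:, None] - xyz[b][None, :], axis=2)
    return float(np.sum(COULOMB_K * q[a][:, None] * q[b][None, :] / r) / eps)


def elec_solvation_binding(
    structure: ParameterizedStructure,
    group_a,
    group_b,
    specs,
    eps_protein: float = 1.0,
    eps_solvent: float = 80.0,
    ionic_strength_mM: float = 150.0,
    stern: float = 2.0,
    tol: float = 1e-6,
) -> float:
    """Electrostatic binding term dW_elec of the snapshot MM-PBSA estimate.

    Rigid-body convention: the complex and the isolated components use
    identical coordinates and identical grids, so grid self-energies
    cancel.  dW_elec = dG_rf(AB) - dG_rf(A) - dG_rf(B) + E_coul(A,B)/eps_p
    with the inter-group Coulomb term evaluated analytically (no cutoff).
    Positive values mean net electrostatic opposition to binding
    (desolvation dominating), the typical outcome for charged interfaces.
    """
    a = np.asarray(group_a, int)
    b = np.asarray(group_b, int)
    if np.intersect1d(a, b).size:
        raise ValueError("groups overlap")
    ab = np.concatenate([a, b])
    # grid must hold the complex with a margin
    pos = structure.coords[ab]
    radii = structure.pb_radii[ab]
    extent = (pos + radii[:, None]).max(axis=0) - (pos - radii[:, None]).min(axis=0)
    if specs[0].length < extent.max() + 10.0:
        raise ValueError(
            f"outer grid ({specs[0].length:.1f} Å) too small for complex "
            f"({extent.max():.1f} Å) plus 10 Å margin"
        )
    args = (eps_protein, eps_solvent, ionic_strength_mM, stern, tol)
    g_ab = reaction_field_energy(structure, ab, specs, *args)
    g_a = reaction_field_energy(structure, a, specs, *args)
    g_b = reaction_field_energy(structure, b, specs, *args)
    return g_ab - g_a - g_b + _coulomb_between(structure, a, b, eps_protein)


def potential_difference_map(
    structure_1: ParameterizedStructure,
    region_1,
    structure_2: ParameterizedStructure,
    region_2,
    specs,
    eps_protein: float = 1.0,
    eps_solvent: float = 80.0,
    ionic_strength_mM: float = 150.0,
    stern: float = 2.0,
    tol: float = 1e-6,
) -> PotentialGrid:
    """Node-wise potential difference phi_1 - phi_2 of two models on one
    common focused grid ladder (finest spec typically centered on a
    nucleotide atom).  Suitable for writing ±1 kcal/(mol·e) isosurface
    levels."""
    phi1, _ = solve_ladder(structure_1, region_1, specs, eps_protein,
                           eps_solvent, ionic_strength_mM, stern, tol)
    phi2, _ = solve_ladder(structure_2, region_2, specs, eps_protein,
                           eps_solvent, ionic_strength_mM, stern, tol)
    if phi1.spec != phi2.spec:
        raise ValueError("difference map requires identical grid specs")
    return PotentialGrid(values=phi1.values - phi2.values, spec=phi1.spec)


def write_dx(grid: PotentialGrid, path, comment: str = "pbsalink potential grid") -> None:
    """Write a scalar grid in OpenDX format (readable by common viewers)."""
    spec = grid.spec
    n = spec.n
    o = spec.origin
    h = spec.spacing
    v = grid.values.ravel(order="C")
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        fh.write(f"object 1 class gridpositions counts {n} {n} {n}\n")
        fh.write(f"origin {o[0]:.6f} {o[1]:.6f} {o[2]:.6f}\n")
        fh.write(f"delta {h:.6f} 0 0\ndelta 0 {h:.6f} 0\ndelta 0 0 {h:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {n} {n} {n}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {n**3} data follows\n"
        )
        for i in range(0, len(v), 3):
            fh.write(" ".join("%.6e" % x for x in v[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "regular positions regular connections" class field\n')
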