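"""Structures, parameters and snapshot ensembles.

The central container is :class:`ParameterizedStructure`: an ordered list of
atoms carrying coordinates, partial charges, Lennard-Jones parameters and a
continuum (Poisson-Boltzmann) radius, plus named atom groups ("ARF1", "GEF",
"GDP", "MG", ...) used by every downstream analysis.

File formats
------------
PDB reading/writing is delegated to biotite.  PQR files (PB inputs) and the
package's own *snapshot archive* are written directly.

Snapshot-archive layout (plain text, one file per ensemble)::

    # pbsalink snapshot archive v1
    natoms <N>
    nframes <M>
    frame <time_ps>
    <x> <y> <z>          (N lines, '%.17g' — exact float64 round trip)
    ...                  (repeated M times)

Coordinates are in Å, times in ps.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Atom",
    "ParameterizedStructure",
    "SnapshotEnsemble",
    "ParseError",
    "read_structure",
    "write_structure",
    "write_pqr",
    "read_parameter_table",
    "assign_parameters",
    "read_snapshots",
    "write_snapshots",
    "select_group",
]

MG_OPTIMIZED_PB_RADIUS = 1.55  # Å, divalent magnesium, optimized radius set


class ParseError(ValueError):
    """A structure, parameter or trajectory file could not be parsed."""


@dataclass
class Atom:
    """One atom with coordinates and per-atom parameters.

    Coordinates in Å, charge in e, lj_epsilon in kcal/mol, lj_rmin_half
    (half the LJ minimum-energy distance) and pb_radius in Å.  Parameters
    default to NaN/0 until :func:`assign_parameters` fills them.
    """

    serial: int
    name: str
    residue_name: str
    residue_id: int
    chain_id: str
    position: np.ndarray
    charge: float = np.nan
    lj_epsilon: float = np.nan
    lj_rmin_half: float = np.nan
    pb_radius: float = np.nan
    element: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        if np.isfinite(self.lj_epsilon) and self.lj_epsilon < 0:
            raise ValueError(f"atom {self.serial}: lj_epsilon must be >= 0")
        if np.isfinite(self.pb_radius) and self.pb_radius < 0:
            raise ValueError(f"atom {self.serial}: pb_radius must be >= 0")


@dataclass
class ParameterizedStructure:
    """Ordered atoms plus named atom-index groups (0-based indices)."""

    atoms: list[Atom]
    groups: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        clean = {}
        for name, idx in self.groups.items():
            idx = np.asarray(sorted(set(int(i) for i in np.atleast_1d(idx))), dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ValueError(f"group {name!r}: indices outside [0, {n})")
            clean[name] = idx
        self.groups = clean

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def pb_radii(self) -> np.ndarray:
        return np.array([a.pb_radius for a in self.atoms], dtype=float)

    @property
    def net_charge(self) -> float:
        """Sum of partial charges, in e."""
        return float(np.nansum(self.charges))

    def group_charge(self, name: str) -> float:
        return float(np.sum(self.charges[self.groups[name]]))

    def register_group(self, name: str, indices) -> None:
        idx = np.asarray(sorted(set(int(i) for i in np.atleast_1d(indices))), dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= len(self.atoms)):
            raise ValueError(f"group {name!r}: indices outside structure")
        self.groups[name] = idx

    def validate(self) -> None:
        """Check container invariants; raise ValueError on violation."""
        for name, idx in self.groups.items():
            if idx.size and idx.max() >= len(self.atoms):
                raise ValueError(f"group {name!r} exceeds atom count")
        if "GDP" in self.groups and self.groups["GDP"].size:
            q = self.group_charge("GDP")
            if np.isfinite(q) and abs(q - (-3.0)) > 1e-6:
                raise ValueError(
                    f"GDP group must carry total charge -3 e (found {q:.6f})"
                )

    def with_coords(self, coords: np.ndarray) -> "ParameterizedStructure":
        """Copy of the structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, position=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return ParameterizedStructure(atoms, dict(self.groups))

    def subset(self, indices) -> "ParameterizedStructure":
        """New structure containing only the given atoms (groups dropped)."""
        idx = np.asarray(sorted(set(int(i) for i in np.atleast_1d(indices))), dtype=int)
        return ParameterizedStructure([self.atoms[i] for i in idx], {})


@dataclass
class SnapshotEnsemble:
    """Coordinate frames sharing one topology.

    frames: (n_frames, n_atoms, 3) Å; frame_times: (n_frames,) ps, strictly
    increasing.
    """

    topology: ParameterizedStructure
    frames: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.topology):
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology ({len(self.topology)} atoms)"
            )
        if self.frame_times.shape != (self.frames.shape[0],):
            raise ValueError("frame_times length must equal number of frames")
        if self.n_frames > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def __iter__(self):
        return iter(self.frames)


# ---------------------------------------------------------------------------
# PDB / PQR
# ---------------------------------------------------------------------------

def _validate_pdb_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise ParseError(f"line {lineno}: ATOM/HETATM record too short")
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
            int(line[22:26])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: malformed ATOM/HETATM fields ({exc})")


def read_structure(path, format: str = "pdb") -> ParameterizedStructure:
    """Read a PDB file into a ParameterizedStructure (parameters unset).

    Atom order, chain ids, residue ids/names and HETATM records (nucleotide,
    ions, waters) are preserved.  Groups are not assigned; use
    :func:`select_group`.
    """
    if format != "pdb":
        raise ValueError(f"unsupported structure format {format!r}")
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    _validate_pdb_lines(text)
    if not any(l.startswith(("ATOM", "HETATM")) for l in text.splitlines()):
        raise ParseError(f"{path}: no atoms (no ATOM/HETATM records)")

    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(io.StringIO(text))
    try:
        arr = pdb.get_structure(model=1)
    except Exception as exc:  # biotite raises various subclasses
        raise ParseError(f"{path}: {exc}") from exc
    if arr.array_length() == 0:
        raise ParseError(f"{path}: no atoms found")

    atoms = []
    for i in range(arr.array_length()):
        atoms.append(
            Atom(
                serial=i + 1,
                name=str(arr.atom_name[i]),
                residue_name=str(arr.res_name[i]),
                residue_id=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]),
                position=arr.coord[i],
                element=str(arr.element[i]),
            )
        )
    return ParameterizedStructure(atoms)


def write_structure(structure: ParameterizedStructure, path) -> None:
    """Write a PDB file (coordinates to 1e-3 Å, the format's precision)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(structure)
    arr = struc.AtomArray(n)
    arr.coord = structure.coords
    for i, a in enumerate(structure.atoms):
        arr.chain_id[i] = a.chain_id
        arr.res_id[i] = a.residue_id
        arr.res_name[i] = a.residue_name
        arr.atom_name[i] = a.name
        arr.element[i] = a.element or a.name[:1]
        arr.hetero[i] = a.residue_name in ("GDP", "MG", "HOH", "LIG", "ION")
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def write_pqr(structure: ParameterizedStructure, path) -> None:
    """Write a PQR file (whitespace-separated PDB variant with q and r)."""
    with open(path, "w") as fh:
        for a in structure.atoms:
            if not (np.isfinite(a.charge) and np.isfinite(a.pb_radius)):
                raise ValueError(f"atom {a.serial}: charge/pb_radius unset")
            fh.write(
                "ATOM  %5d %-4s %-4s %4d    %8.3f %8.3f %8.3f %8.4f %7.4f\n"
                % (
                    a.serial,
                    a.name,
                    a.residue_name,
                    a.residue_id,
                    a.position[0],
                    a.position[1],
                    a.position[2],
                    a.charge,
                    a.pb_radius,
                )
            )


# ---------------------------------------------------------------------------
# Parameter table
# ---------------------------------------------------------------------------

def read_parameter_table(path) -> dict:
    """Read a TSV parameter table keyed by (residue_name, atom_name).

    Columns: residue_name, atom_name, charge, lj_epsilon, lj_rmin_half,
    pb_radius_charmm, pb_radius_optimized.  '#' starts a comment.
    """
    table = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ParseError(f"line {lineno}: expected 7 columns, got {len(parts)}")
            key = (parts[0], parts[1])
            if key in table:
                raise ParseError(f"line {lineno}: duplicate entry for {key}")
            table[key] = {
                "charge": float(parts[2]),
                "lj_epsilon": float(parts[3]),
                "lj_rmin_half": float(parts[4]),
                "pb_radius_charmm": float(parts[5]),
                "pb_radius_optimized": float(parts[6]),
            }
    return table


def assign_parameters(
    structure: ParameterizedStructure,
    parameter_table,
    radius_set: str = "charmm",
) -> ParameterizedStructure:
    """Assign charges, LJ parameters and PB radii from a parameter table.

    ``parameter_table`` is a path or a dict from :func:`read_parameter_table`.
    ``radius_set`` selects which PB radius column is used ('charmm' or
    'optimized').  With the optimized set any Mg²⁺ atom receives a PB radius
    of 1.55 Å.
    """
    if radius_set not in ("charmm", "optimized"):
        raise ValueError(f"unknown radius_set {radius_set!r}")
    table = parameter_table
    if not isinstance(table, dict):
        table = read_parameter_table(table)

    missing = []
    new_atoms = []
    rkey = f"pb_radius_{radius_set}"
    for a in structure.atoms:
        entry = table.get((a.residue_name, a.atom_name if hasattr(a, "atom_name") else a.name))
        if entry is None:
            entry = table.get((a.residue_name, a.name))
        if entry is None:
            missing.append(f"{a.residue_name}/{a.name}")
            continue
        pbr = entry[rkey]
        if radius_set == "optimized" and (
            a.residue_name.upper() == "MG" or a.element.upper() == "MG"
        ):
            pbr = MG_OPTIMIZED_PB_RADIUS
        new_atoms.append(
            replace(
                a,
                charge=entry["charge"],
                lj_epsilon=entry["lj_epsilon"],
                lj_rmin_half=entry["lj_rmin_half"],
                pb_radius=pbr,
            )
        )
    if missing:
        raise KeyError(
            "no parameters for atoms: " + ", ".join(sorted(set(missing)))
        )
    return ParameterizedStructure(new_atoms, dict(structure.groups))


# ---------------------------------------------------------------------------
# Snapshot ensembles
# ---------------------------------------------------------------------------

def write_snapshots(ensemble: SnapshotEnsemble, path) -> None:
    """Write a snapshot archive (see module docstring for the layout)."""
    with open(path, "w") as fh:
        fh.write("# pbsalink snapshot archive v1\n")
        fh.write(f"natoms {ensemble.frames.shape[1]}\n")
        fh.write(f"nframes {ensemble.n_frames}\n")
        for t, frame in zip(ensemble.frame_times, ensemble.frames):
            fh.write("frame %.17g\n" % t)
            for x, y, z in frame:
                fh.write("%.17g %.17g %.17g\n" % (x, y, z))


def _read_archive(path, topology):
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    it = iter(enumerate(lines, start=1))

    def next_content():
        for lineno, line in it:
            s = line.strip()
            if s and not s.startswith("#"):
                return lineno, s
        return None, None

    _, l1 = next_content()
    _, l2 = next_content()
    if l1 is None or not l1.startswith("natoms") or l2 is None or not l2.startswith("nframes"):
        raise ParseError(f"{path}: missing archive header")
    natoms = int(l1.split()[1])
    nframes = int(l2.split()[1])
    if natoms != len(topology):
        raise ParseError(
            f"{path}: atom count mismatch (expected {len(topology)}, found {natoms})"
        )
    frames = np.empty((nframes, natoms, 3))
    times = np.empty(nframes)
    for f in range(nframes):
        lineno, hdr = next_content()
        if hdr is None or not hdr.startswith("frame"):
            raise ParseError(f"{path}: truncated archive at frame {f} (header)")
        times[f] = float(hdr.split()[1])
        for i in range(natoms):
            lineno, row = next_content()
            if row is None:
                raise ParseError(
                    f"{path}: truncated archive in frame {f} "
                    f"(expected {natoms} atoms, found {i})"
                )
            parts = row.split()
            if len(parts) != 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 coordinates")
            frames[f, i] = [float(p) for p in parts]
    return frames, times


def read_snapshots(
    path,
    topology: ParameterizedStructure,
    format: str = "snapshot-archive",
    stride_ps: float | None = None,
) -> SnapshotEnsemble:
    """Read a trajectory into a SnapshotEnsemble.

    format 'snapshot-archive' reads the package's text archive; 'dcd'
    delegates to mdtraj (times reconstructed from ``stride_ps``, default
    1 ps, since DCD headers are dialect-dependent).
    """
    if format == "snapshot-archive":
        frames, times = _read_archive(path, topology)
        if stride_ps is not None:
            times = np.arange(len(frames)) * stride_ps
        return SnapshotEnsemble(topology, frames, times)
    if format == "dcd":
        import mdtraj

        # mdtraj requires a topology object; build a minimal one
        import mdtraj.core.topology as mdtop

        top = mdtop.Topology()
        ch = top.add_chain()
        res = top.add_residue("UNK", ch)
        from mdtraj.core import element as mdelem

        for a in topology.atoms:
            top.add_atom(a.name, mdelem.carbon, res)
        traj = mdtraj.load_dcd(str(path), top=top)
        if traj.n_atoms != len(topology):
            raise ParseError(
                f"{path}: atom count mismatch (expected {len(topology)}, "
                f"found {traj.n_atoms})"
            )
        dt = 1.0 if stride_ps is None else stride_ps
        frames = traj.xyz.astype(float) * 10.0  # nm -> Å
        return SnapshotEnsemble(topology, frames, np.arange(traj.n_frames) * dt)
    raise ValueError(f"unsupported trajectory format {format!r}")


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------

class _SelParser:
    """Recursive-descent parser for tiny atom-selection expressions.

    Grammar: expr := term ('or' term)*; term := factor ('and' factor)*;
    factor := 'not' factor | '(' expr ')' | keyword value+ ;
    keywords: chain, resname, resid, name.
    """

    KEYWORDS = ("chain", "resname", "resid", "name")

    def __init__(self, tokens, structure):
        self.tokens = tokens
        self.pos = 0
        self.s = structure

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self):
        mask = self.expr()
        if self.peek() is not None:
            raise ValueError(f"selector syntax error near {self.peek()!r}")
        return mask

    def expr(self):
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self):
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self):
        tok = self.peek()
        if tok is None:
            raise ValueError("selector syntax error: unexpected end of expression")
        if tok == "not":
            self.take()
            return ~self.factor()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.take() != ")":
                raise ValueError("selector syntax error: missing ')'")
            return mask
        if tok in self.KEYWORDS:
            self.take()
            values = []
            while self.peek() is not None and self.peek() not in (
                "and", "or", "not", "(", ")", *self.KEYWORDS,
            ):
                values.append(self.take())
            if not values:
                raise ValueError(f"selector syntax error: {tok!r} needs a value")
            return self._match(tok, values)
        raise ValueError(f"selector syntax error near {tok!r}")

    def _match(self, key, values):
        atoms = self.s.atoms
        if key == "chain":
            vals = set(values)
            return np.array([a.chain_id in vals for a in atoms])
        if key == "resname":
            vals = set(values)
            return np.array([a.residue_name in vals for a in atoms])
        if key == "name":
            vals = set(values)
            return np.array([a.name in vals for a in atoms])
        if key == "resid":
            try:
                vals = set(int(v) for v in values)
            except ValueError:
                raise ValueError("selector syntax error: resid needs integers")
            return np.array([a.residue_id in vals for a in atoms])
        raise AssertionError(key)


def select_group(
    structure: ParameterizedStructure,
    selector: str,
    register_as: str | None = None,
) -> np.ndarray:
    """Evaluate a selection expression; return sorted 0-based atom indices.

    Supports ``chain``, ``resname``, ``resid``, ``name`` combined with
    ``and``/``or``/``not`` and parentheses, e.g.
    ``"resname GDP and name O2B"``.  An empty result raises a warning, not
    an error.  With ``register_as`` the set is stored on the structure.
    """
    tokens = selector.replace("(", " ( ").replace(")", " ) ").split()
    if not tokens:
        raise ValueError("empty selector")
    mask = _SelParser(tokens, structure).parse()
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        warnings.warn(f"selector {selector!r} matched no atoms", stacklevel=2)
    if register_as is not None:
        structure.register_group(register_as, idx)
    return idx
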