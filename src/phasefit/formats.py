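"""Readers and writers for the file formats the workflow touches.

* CHARMM stream-file dialect (subset): a topology block (MASS / RESI /
  ATOM / BOND / DOUBLE / IMPR) and parameter blocks (BONDS, ANGLES,
  DIHEDRALS, IMPROPERS, NONBONDED), with CGenFF-style trailing penalty
  comments (``! penalty= X`` or ``! penalty: X``, case-insensitive).
* XYZ geometries, single- and multi-frame; PDB coordinates (read-only).
* Torsion-scan tables: a plain delimited text format defined by this
  package (QM engines are out of scope), with an accompanying multi-frame
  XYZ geometry file.
* Plain-text Cartesian Hessians, full square or lower-triangular, in
  kcal/mol/A^2 or Hartree/Bohr^2.

Parsers never silently drop content: every non-comment, non-blank line is
either consumed or reported as an error.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    AngleParam,
    AtomSpec,
    BondParam,
    DihedralTerm,
    ImproperParam,
    MoleculeSystem,
    ParameterSet,
    canonical_angle_key,
    canonical_bond_key,
    canonical_dihedral_key,
    canonical_improper_key,
    measure_dihedral,
    wrap_angle_deg,
)
from .errors import (
    DuplicateTermError,
    IncompleteGridError,
    ScanInconsistencyError,
    StreamParseError,
)

HARTREE_KCAL = 627.509474
BOHR_ANGSTROM = 0.529177210903
HARTREE_BOHR2_TO_KCAL_A2 = HARTREE_KCAL / BOHR_ANGSTROM**2

_PENALTY_RE = re.compile(r"penalty\s*[:=]\s*([-+0-9.eE]+)", re.IGNORECASE)


# ---------------------------------------------------------------------------
# topology container (geometry comes separately)
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Stream-file topology fields; pair with a geometry via build_system."""

    residue_name: str
    atoms: list[AtomSpec]
    bonds: set[tuple[int, int]]
    bond_orders: dict[tuple[int, int], int]
    impropers: list[tuple[int, int, int, int]]

    def build_system(self, geometry: np.ndarray,
                     selections: dict[str, frozenset[int]] | None = None) -> MoleculeSystem:
        return MoleculeSystem(
            atoms=list(self.atoms),
            bonds=frozenset(self.bonds),
            reference_geometry=np.asarray(geometry, dtype=float),
            bond_orders=dict(self.bond_orders),
            impropers=list(self.impropers),
            selections=dict(selections or {}),
        )


# ---------------------------------------------------------------------------
# stream files
# ---------------------------------------------------------------------------

def _split_comment(line: str) -> tuple[str, str]:
    if "!" in line:
        body, comment = line.split("!", 1)
        return body.strip(), comment.strip()
    return line.strip(), ""


def _penalty_of(comment: str) -> float:
    m = _PENALTY_RE.search(comment)
    return float(m.group(1)) if m else 0.0


def _floats(tokens: Sequence[str], lineno: int) -> list[float]:
    out = []
    for tok in tokens:
        try:
            out.append(float(tok))
        except ValueError:
            raise StreamParseError(f"malformed numeric field {tok!r}", lineno) from None
    return out


def read_stream(source) -> tuple[Topology, ParameterSet]:
    """Parse the stream dialect into (Topology, ParameterSet).

    ``source`` is a path, a string of text, or a file-like object.
    Penalty annotations land in ``ParameterSet.penalties``; dihedral lines
    with the same type key accumulate into one term list; duplicate
    (key, n) lines are an error.
    """
    text = _as_text(source)
    masses: dict[str, tuple[float, str]] = {}
    resi_name = ""
    atoms: list[AtomSpec] = []
    name_to_index: dict[str, int] = {}
    bonds: set[tuple[int, int]] = set()
    bond_orders: dict[tuple[int, int], int] = {}
    impropers: list[tuple[int, int, int, int]] = []
    params = ParameterSet()
    section = None  # None | BONDS | ANGLES | DIHEDRALS | IMPROPERS | NONBONDED

    def atom_index(name: str, lineno: int) -> int:
        if name not in name_to_index:
            raise StreamParseError(f"unknown atom name {name!r}", lineno)
        return name_to_index[name]

    for lineno, raw in enumerate(text.splitlines(), start=1):
        body, comment = _split_comment(raw)
        if not body or body.startswith("*"):
            continue
        upper = body.upper()
        kw = upper.split()[0]
        toks = body.split()

        if kw == "READ" or kw == "END" or kw == "RETURN":
            section = None
            continue
        if kw == "MASS":
            # MASS -1 TYPE mass element
            if len(toks) < 5:
                raise StreamParseError("MASS line needs: MASS -1 type mass element", lineno)
            masses[toks[2]] = (_floats([toks[3]], lineno)[0], toks[4])
            continue
        if kw == "RESI":
            resi_name = toks[1] if len(toks) > 1 else "MOL"
            section = None
            continue
        if kw == "ATOM":
            if len(toks) < 4:
                raise StreamParseError("ATOM line needs: ATOM name type charge", lineno)
            name, atype = toks[1], toks[2]
            charge = _floats([toks[3]], lineno)[0]
            if atype not in masses:
                raise StreamParseError(f"atom type {atype!r} has no MASS line", lineno)
            mass, element = masses[atype]
            idx = len(atoms)
            atoms.append(AtomSpec(idx, element, atype, charge, mass, name=name))
            name_to_index[name] = idx
            continue
        if kw in ("BOND", "DOUBLE"):
            names = toks[1:]
            if len(names) % 2:
                raise StreamParseError("odd number of atoms on BOND line", lineno)
            for a, b in zip(names[::2], names[1::2]):
                ia, ib = atom_index(a, lineno), atom_index(b, lineno)
                pair = (min(ia, ib), max(ia, ib))
                bonds.add(pair)
                bond_orders[pair] = 2 if kw == "DOUBLE" else 1
            continue
        if kw == "IMPR":
            names = toks[1:]
            if len(names) % 4:
                raise StreamParseError("IMPR line needs quadruples of atom names", lineno)
            for q in zip(names[::4], names[1::4], names[2::4], names[3::4]):
                impropers.append(tuple(atom_index(x, lineno) for x in q))
            continue
        if upper in ("BONDS", "ANGLES", "DIHEDRALS", "IMPROPERS", "NONBONDED"):
            section = upper
            continue

        if section == "BONDS":
            if len(toks) != 4:
                raise StreamParseError("bond parameter line needs: t1 t2 k b0", lineno)
            k, b0 = _floats(toks[2:], lineno)
            key = canonical_bond_key(toks[0], toks[1])
            params.bonds[key] = BondParam(k, b0)
            params.penalties[key] = _penalty_of(comment)
        elif section == "ANGLES":
            if len(toks) != 5:
                raise StreamParseError("angle parameter line needs: t1 t2 t3 k theta0", lineno)
            k, t0 = _floats(toks[3:], lineno)
            key = canonical_angle_key(toks[0], toks[1], toks[2])
            params.angles[key] = AngleParam(k, t0)
            params.penalties[key] = _penalty_of(comment)
        elif section == "DIHEDRALS":
            if len(toks) != 7:
                raise StreamParseError(
                    "dihedral parameter line needs: t1 t2 t3 t4 k n delta", lineno)
            k, n, delta = _floats(toks[4:], lineno)
            if abs(n - round(n)) > 1e-9:
                raise StreamParseError(f"multiplicity must be integral, got {n}", lineno)
            key = canonical_dihedral_key(*toks[:4])
            terms = params.dihedrals.setdefault(key, [])
            if any(t.n == int(round(n)) for t in terms):
                raise DuplicateTermError(
                    f"duplicate dihedral term for {key} with n={int(round(n))}", lineno)
            terms.append(DihedralTerm(k, int(round(n)), delta).canonical())
            terms.sort(key=lambda t: t.n)
            pen = _penalty_of(comment)
            params.penalties[key] = max(params.penalties.get(key, 0.0), pen)
        elif section == "IMPROPERS":
            if len(toks) != 7:
                raise StreamParseError(
                    "improper parameter line needs: t1 t2 t3 t4 k 0 omega0", lineno)
            k, _zero, w0 = _floats(toks[4:], lineno)
            key = canonical_improper_key(*toks[:4])
            params.impropers[key] = ImproperParam(k, w0)
            params.penalties[key] = _penalty_of(comment)
        elif section == "NONBONDED":
            if len(toks) != 4:
                raise StreamParseError(
                    "nonbonded line needs: type ignored -epsilon rmin_half", lineno)
            _ign, neg_eps, rmin_half = _floats(toks[1:], lineno)
            params.nonbonded[toks[0]] = (abs(neg_eps), rmin_half)
        else:
            raise StreamParseError(f"unrecognised line {body!r}", lineno)

    topo = Topology(resi_name or "MOL", atoms, bonds, bond_orders, impropers)
    return topo, params


def write_stream(system: MoleculeSystem | Topology, params: ParameterSet,
                 title: str = "phasefit parameters") -> str:
    """Emit a deterministic stream file readable by read_stream.

    Refuses to write when any instance of the system is unparametrised.
    Formatting: bond/angle force constants 2 decimals, lengths 4 decimals,
    k_phi 4 decimals, delta printed as 0.00/180.00; sorted keys, ascending
    multiplicity.
    """
    if isinstance(system, Topology):
        atoms = system.atoms
        bonds = {(min(a, b), max(a, b)) for a, b in system.bonds}
        bond_orders = system.bond_orders
        impropers = system.impropers
        resi = system.residue_name
        sys_for_check = None
    else:
        atoms = system.atoms
        bonds = set(system.bonds)
        bond_orders = system.bond_orders or {}
        impropers = system.impropers
        resi = "MOL"
        sys_for_check = system

    if not atoms:
        raise ValueError("refusing to write a stream file for an empty molecule")

    types = [a.atom_type for a in atoms]
    if sys_for_check is not None:
        for i, j in sorted(bonds):
            key = canonical_bond_key(types[i], types[j])
            if key not in params.bonds:
                raise StreamParseError(f"missing bond parameter for instance ({i},{j}) {key}")
        for i, j, k in sys_for_check.angle_instances:
            key = canonical_angle_key(types[i], types[j], types[k])
            if key not in params.angles:
                raise StreamParseError(f"missing angle parameter for instance ({i},{j},{k}) {key}")
        for q in sys_for_check.dihedral_instances:
            key = canonical_dihedral_key(*(types[x] for x in q))
            if key not in params.dihedrals:
                raise StreamParseError(f"missing dihedral parameter for instance {q} {key}")
        for q in impropers:
            key = canonical_improper_key(*(types[x] for x in q))
            if key not in params.impropers:
                raise StreamParseError(f"missing improper parameter for instance {q} {key}")

    lines = [f"* {title}", "*", ""]
    lines.append("read rtf card append")
    seen_types: dict[str, tuple[float, str]] = {}
    for a in atoms:
        seen_types.setdefault(a.atom_type, (a.mass, a.element))
    for atype in sorted(seen_types):
        mass, element = seen_types[atype]
        lines.append(f"MASS -1 {atype} {mass:.5f} {element}")
    total_charge = sum(a.charge for a in atoms)
    lines.append(f"RESI {resi} {total_charge:.3f}")
    for i, a in enumerate(atoms):
        name = a.name or f"A{i + 1}"
        lines.append(f"ATOM {name} {a.atom_type} {a.charge:.4f}")
    names = [a.name or f"A{i + 1}" for i, a in enumerate(atoms)]
    for i, j in sorted(bonds):
        kw = "DOUBLE" if bond_orders.get((i, j), 1) == 2 else "BOND"
        lines.append(f"{kw} {names[i]} {names[j]}")
    for q in impropers:
        lines.append("IMPR " + " ".join(names[x] for x in q))
    lines.append("END")
    lines.append("")
    lines.append("read param card flex append")

    def pen(key) -> str:
        return f" ! penalty= {params.penalty(key):g}"

    lines.append("BONDS")
    for key in sorted(params.bonds):
        p = params.bonds[key]
        lines.append(f"{key[0]} {key[1]} {p.k_b:.2f} {p.b0:.4f}{pen(key)}")
    lines.append("ANGLES")
    for key in sorted(params.angles):
        p = params.angles[key]
        lines.append(f"{key[0]} {key[1]} {key[2]} {p.k_theta:.2f} {p.theta0:.2f}{pen(key)}")
    lines.append("DIHEDRALS")
    for key in sorted(params.dihedrals):
        for term in sorted(params.dihedrals[key], key=lambda t: t.n):
            lines.append(
                " ".join(key)
                + f" {term.k_phi:.4f} {term.n} {term.delta:.2f}{pen(key)}"
            )
    lines.append("IMPROPERS")
    for key in sorted(params.impropers):
        p = params.impropers[key]
        lines.append(" ".join(key) + f" {p.k_omega:.2f} 0 {p.omega0:.2f}{pen(key)}")
    if params.nonbonded:
        lines.append("NONBONDED")
        for atype in sorted(params.nonbonded):
            eps, rmin_half = params.nonbonded[atype]
            lines.append(f"{atype} 0.0 {-eps:.4f} {rmin_half:.4f}")
    lines.append("END")
    lines.append("")
    return "\n".join(lines)


def _as_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    if isinstance(source, Path):
        return source.read_text()
    s = str(source)
    if "\n" not in s and Path(s).exists():
        return Path(s).read_text()
    return s


# ---------------------------------------------------------------------------
# XYZ and PDB
# ---------------------------------------------------------------------------

def read_xyz(source) -> list[tuple[list[str], np.ndarray, str]]:
    """Read a (multi-frame) XYZ file -> [(elements, coords, comment), ...]."""
    text = _as_text(source)
    lines = text.splitlines()
    frames = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        n = int(lines[pos].strip())
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        elems, coords = [], []
        for row in lines[pos + 2: pos + 2 + n]:
            toks = row.split()
            elems.append(toks[0])
            coords.append([float(x) for x in toks[1:4]])
        frames.append((elems, np.asarray(coords, dtype=float), comment))
        pos += 2 + n
    return frames


def write_xyz(frames, elements: Sequence[str], comments: Sequence[str] | None = None) -> str:
    """Serialise one or many coordinate arrays as (multi-frame) XYZ text."""
    if isinstance(frames, np.ndarray) and frames.ndim == 2:
        frames = [frames]
    frames = [np.asarray(f, dtype=float).reshape(-1, 3) for f in frames]
    out = io.StringIO()
    for fi, coords in enumerate(frames):
        comment = comments[fi] if comments is not None else f"frame {fi}"
        out.write(f"{len(elements)}\n{comment}\n")
        for e, (x, y, z) in zip(elements, coords):
            out.write(f"{e} {x:.10f} {y:.10f} {z:.10f}\n")
    return out.getvalue()


def read_pdb(source) -> tuple[list[str], np.ndarray]:
    """Minimal PDB coordinate reader (ATOM/HETATM records only)."""
    text = _as_text(source)
    elems, coords = [], []
    for line in text.splitlines():
        if line.startswith(("ATOM", "HETATM")):
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            element = line[76:78].strip() or line[12:16].strip()[:1]
            elems.append(element)
            coords.append((x, y, z))
    return elems, np.asarray(coords, dtype=float)


# ---------------------------------------------------------------------------
# torsion-scan tables
# ---------------------------------------------------------------------------

@dataclass
class ScanTable:
    """One torsion scan: driven dihedral(s), per-row angle(s)/energy/frame.

    ``angles`` has shape (rows, ndim); ``frames`` is a list of (N,3)
    coordinate arrays indexed by the ``frame`` column.  ``truth`` is an
    optional generator bookkeeping dict (synthetic fixtures only).
    """

    driven: tuple[tuple[int, int, int, int], ...]
    angles: np.ndarray
    energies: np.ndarray
    frame_indices: np.ndarray
    frames: list[np.ndarray]
    step: float | None = None
    scan_range: tuple[float, float] | None = None
    origin: str = "absolute"  # or "min-subtracted"
    truth: dict | None = None

    def __post_init__(self):
        self.angles = np.atleast_2d(np.asarray(self.angles, dtype=float))
        if self.angles.shape[0] == 1 and len(self.energies) > 1:
            self.angles = self.angles.T
        self.energies = np.asarray(self.energies, dtype=float)
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        if len(set(self.frame_indices.tolist())) != len(self.frame_indices):
            raise ValueError("frame indices must be unique")
        nd = len(self.driven)
        if self.angles.shape[1] != nd:
            raise ValueError("angle columns do not match number of driven dihedrals")
        if nd == 1:
            a = self.angles[:, 0]
            if not np.all(np.diff(a) > 0):
                raise ValueError("1D scan angles must be strictly increasing")
        elif nd == 2:
            self._check_grid()
        else:
            raise ValueError("only 1D and 2D scans are supported")

    @property
    def ndim(self) -> int:
        return len(self.driven)

    def _check_grid(self):
        a1 = np.unique(np.round(self.angles[:, 0], 6))
        a2 = np.unique(np.round(self.angles[:, 1], 6))
        have = {(round(x, 6), round(y, 6)) for x, y in self.angles}
        missing = [(x, y) for x in a1 for y in a2 if (x, y) not in have]
        if missing:
            raise IncompleteGridError(
                f"2D scan grid is missing {len(missing)} cells", missing)
        if len(have) != len(a1) * len(a2):
            raise IncompleteGridError("duplicate 2D grid cells present")

    def grid_shape(self) -> tuple[int, ...]:
        if self.ndim == 1:
            return (len(self.energies),)
        a1 = np.unique(np.round(self.angles[:, 0], 6))
        a2 = np.unique(np.round(self.angles[:, 1], 6))
        return (len(a1), len(a2))

    def row_coordinates(self, row: int) -> np.ndarray:
        return self.frames[self.frame_indices[row]]

    def relative_energies(self) -> np.ndarray:
        return self.energies - float(np.min(self.energies))


def write_scan(scan: ScanTable) -> tuple[str, str]:
    """Serialise a ScanTable -> (table text, multi-frame XYZ text).

    The XYZ side carries placeholder element symbols when the scan frames
    were built without element information.
    """
    out = io.StringIO()
    for d, quad in enumerate(scan.driven, start=1):
        out.write(f"# driven{d}: {' '.join(map(str, quad))}\n")
    if scan.step is not None:
        out.write(f"# step: {scan.step:g}\n")
    if scan.scan_range is not None:
        out.write(f"# range: {scan.scan_range[0]:g} {scan.scan_range[1]:g}\n")
    out.write(f"# origin: {scan.origin}\n")
    cols = " ".join(f"angle{d+1}" for d in range(scan.ndim))
    out.write(f"# columns: {cols} energy frame\n")
    for row in range(len(scan.energies)):
        angs = " ".join(f"{a:.6f}" for a in scan.angles[row])
        out.write(f"{angs} {scan.energies[row]:.10f} {scan.frame_indices[row]}\n")
    n_atoms = len(scan.frames[0])
    elements = ["X"] * n_atoms
    frames_text = write_xyz(list(scan.frames), elements,
                            comments=[f"scan frame {i}" for i in range(len(scan.frames))])
    return out.getvalue(), frames_text


def read_scan(table_source, frames_source, angle_tol: float = 1.0) -> ScanTable:
    """Parse a scan table + frames file; validate grid and geometries.

    The driven dihedral is re-measured on every frame and must agree with
    the declared angle within ``angle_tol`` degrees (periodicity-aware).
    """
    text = _as_text(table_source)
    driven: list[tuple[int, int, int, int]] = []
    step = None
    rng = None
    origin = "absolute"
    rows = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.lower().startswith("driven"):
                _, val = body.split(":", 1)
                driven.append(tuple(int(x) for x in val.split()))
            elif body.lower().startswith("step"):
                step = float(body.split(":", 1)[1])
            elif body.lower().startswith("range"):
                lo, hi = (float(x) for x in body.split(":", 1)[1].split())
                rng = (lo, hi)
            elif body.lower().startswith("origin"):
                origin = body.split(":", 1)[1].strip()
            continue
        toks = line.split()
        rows.append(([float(x) for x in toks[:-1]], int(toks[-1]), lineno))
    if not driven:
        raise ScanInconsistencyError("scan table declares no driven dihedral")
    nd = len(driven)
    angles = np.array([r[0][:nd] for r in rows], dtype=float)
    energies = np.array([r[0][nd] for r in rows], dtype=float)
    frame_indices = np.array([r[1] for r in rows], dtype=int)

    xyz_frames = read_xyz(frames_source)
    frames = [coords for _e, coords, _c in xyz_frames]

    scan = ScanTable(tuple(driven), angles, energies, frame_indices, frames,
                     step=step, scan_range=rng, origin=origin)
    for row in range(len(energies)):
        geom = scan.row_coordinates(row)
        for d, quad in enumerate(scan.driven):
            measured = measure_dihedral(geom, quad)
            declared = scan.angles[row, d]
            diff = abs(wrap_angle_deg(measured - declared))
            if diff > angle_tol:
                raise ScanInconsistencyError(
                    f"row {row}: declared angle {declared:.2f} deviates from "
                    f"measured {measured:.2f} by {diff:.2f} deg (> {angle_tol})"
                )
    return scan


# ---------------------------------------------------------------------------
# Hessians
# ---------------------------------------------------------------------------

@dataclass
class HessianMatrix:
    """Cartesian second-derivative matrix (kcal/mol/A^2) + its geometry."""

    matrix: np.ndarray
    geometry: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.geometry = np.asarray(self.geometry, dtype=float).reshape(-1, 3)
        dim = 3 * len(self.geometry)
        if self.matrix.shape != (dim, dim):
            raise ValueError(
                f"Hessian shape {self.matrix.shape} does not match 3N={dim}")
        scale = max(np.abs(self.matrix).max(), 1.0)
        if np.abs(self.matrix - self.matrix.T).max() > 1e-6 * scale:
            raise ValueError("Hessian is not symmetric to 1e-6 relative tolerance")


def read_hessian(source, geometry: np.ndarray,
                 units: str = "kcal_mol_angstrom2") -> HessianMatrix:
    """Parse a whitespace-separated Hessian (full square or lower triangle).

    ``units`` is 'kcal_mol_angstrom2' (native) or 'hartree_bohr2'
    (converted on read).  The matrix is symmetrised as (H + H^T)/2 and its
    dimension checked against ``geometry``.
    """
    text = _as_text(source)
    vals = [float(t) for t in text.split()]
    geometry = np.asarray(geometry, dtype=float).reshape(-1, 3)
    dim = 3 * len(geometry)
    if len(vals) == dim * dim:
        mat = np.asarray(vals, dtype=float).reshape(dim, dim)
    elif len(vals) == dim * (dim + 1) // 2:
        mat = np.zeros((dim, dim))
        pos = 0
        for i in range(dim):
            for j in range(i + 1):
                mat[i, j] = vals[pos]
                pos += 1
        mat = mat + mat.T - np.diag(np.diag(mat))
    else:
        raise ValueError(
            f"Hessian token count {len(vals)} fits neither a {dim}x{dim} "
            f"square nor its lower triangle")
    if units == "hartree_bohr2":
        mat = mat * HARTREE_BOHR2_TO_KCAL_A2
    elif units != "kcal_mol_angstrom2":
        raise ValueError(f"unknown Hessian units {units!r}")
    mat = 0.5 * (mat + mat.T)
    return HessianMatrix(mat, geometry)


def write_hessian(hessian: HessianMatrix) -> str:
    rows = []
    for row in hessian.matrix:
        rows.append(" ".join(f"{v:.10e}" for v in row))
    return "\n".join(rows) + "\n"
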