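"""Domain types, internal-coordinate geometry, and the molecular-mechanics
energy model.

Conventions
-----------
* All angles (valence, torsion, phase shifts) are degrees at every public
  interface; radians are used internally where calculus demands it.
* Torsions follow the IUPAC sign convention, values in (-180, 180],
  cis = 0.
* Dihedral terms are ``k * (1 + cos(n*phi - delta))`` with ``n`` in
  {1, 2, 3, 4, 6} and ``delta`` in {0, 180}; ``k >= 0`` in canonical form
  (a negative k is normalised by flipping delta, which shifts only the
  additive constant).
* Harmonic bonded terms are CHARMM-style ``k * (x - x0)**2`` (the 1/2 is
  absorbed into k).
* Nonbonded: plain 12-6 Lennard-Jones with Lorentz-Berthelot-style
  combination from (epsilon, rmin/2) plus unscreened Coulomb; 1-2 and 1-3
  pairs excluded, 1-4 and beyond fully included (no 1-4 scaling). No
  cutoff — systems here are tens of atoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    DegenerateGeometryError,
    UnderdeterminedSuperpositionError,
    UnparametrisedInstanceError,
)

COULOMB_KCAL = 332.0637  # kcal mol^-1 Angstrom e^-2
ALLOWED_MULTIPLICITIES = frozenset({1, 2, 3, 4, 6})
ALLOWED_PHASES = frozenset({0.0, 180.0})


# ---------------------------------------------------------------------------
# canonical type-key orientation
# ---------------------------------------------------------------------------

def canonical_bond_key(a: str, b: str) -> tuple[str, str]:
    return min((a, b), (b, a))


def canonical_angle_key(a: str, b: str, c: str) -> tuple[str, str, str]:
    return min((a, b, c), (c, b, a))


def canonical_dihedral_key(a: str, b: str, c: str, d: str) -> tuple[str, ...]:
    return min((a, b, c, d), (d, c, b, a))


canonical_improper_key = canonical_dihedral_key


def wrap_angle_deg(a):
    """Wrap an angle (degrees) into (-180, 180]."""
    w = np.asarray(a, dtype=float)
    w = np.mod(w + 180.0, 360.0) - 180.0
    w = np.where(np.isclose(w, -180.0), 180.0, w)
    if np.ndim(a) == 0:
        return float(w)
    return w


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomSpec:
    """One atom: index, element symbol, force-field type, charge, mass."""

    index: int
    element: str
    atom_type: str
    charge: float
    mass: float
    name: str = ""

    def __post_init__(self):
        if self.index < 0:
            raise ValueError(f"atom index must be >= 0, got {self.index}")
        if not self.element:
            raise ValueError("element symbol must be non-empty")
        if not math.isfinite(self.charge):
            raise ValueError("charge must be finite")


@dataclass(frozen=True)
class DihedralTerm:
    """One cosine term k*(1+cos(n*phi - delta)) of the dihedral series."""

    k_phi: float
    n: int
    delta: float

    def __post_init__(self):
        if self.n not in ALLOWED_MULTIPLICITIES:
            raise ValueError(f"multiplicity must be in {{1,2,3,4,6}}, got {self.n}")
        if float(self.delta) not in ALLOWED_PHASES:
            raise ValueError(f"phase shift must be 0 or 180, got {self.delta}")

    def canonical(self) -> "DihedralTerm":
        """Return an equivalent term with k >= 0 (delta flipped if needed)."""
        if self.k_phi >= 0:
            return self
        return DihedralTerm(-self.k_phi, self.n, 180.0 - self.delta)


@dataclass(frozen=True)
class BondParam:
    k_b: float       # kcal/mol/A^2
    b0: float        # Angstrom

    def __post_init__(self):
        if self.k_b < 0:
            raise ValueError("bond force constant must be >= 0")
        if self.b0 <= 0:
            raise ValueError("equilibrium bond length must be > 0")


@dataclass(frozen=True)
class AngleParam:
    k_theta: float   # kcal/mol/rad^2
    theta0: float    # degrees

    def __post_init__(self):
        if self.k_theta < 0:
            raise ValueError("angle force constant must be >= 0")
        if not 0.0 < self.theta0 < 180.0:
            raise ValueError("equilibrium angle must lie in (0, 180)")


@dataclass(frozen=True)
class ImproperParam:
    k_omega: float   # kcal/mol/rad^2
    omega0: float    # degrees

    def __post_init__(self):
        if self.k_omega < 0:
            raise ValueError("improper force constant must be >= 0")


@dataclass
class ParameterSet:
    """Typed bonded + nonbonded parameters with penalty annotations.

    All type keys are stored in canonical orientation (lexicographically
    smaller of forward/reversed tuple).  A dihedral key maps to a list of
    terms carrying at most one term per multiplicity.
    """

    bonds: dict[tuple[str, str], BondParam] = field(default_factory=dict)
    angles: dict[tuple[str, str, str], AngleParam] = field(default_factory=dict)
    dihedrals: dict[tuple[str, ...], list[DihedralTerm]] = field(default_factory=dict)
    impropers: dict[tuple[str, ...], ImproperParam] = field(default_factory=dict)
    nonbonded: dict[str, tuple[float, float]] = field(default_factory=dict)
    penalties: dict[tuple, float] = field(default_factory=dict)

    def __post_init__(self):
        self.bonds = {canonical_bond_key(*k): v for k, v in self.bonds.items()}
        self.angles = {canonical_angle_key(*k): v for k, v in self.angles.items()}
        self.dihedrals = {
            canonical_dihedral_key(*k): [t.canonical() for t in v]
            for k, v in self.dihedrals.items()
        }
        self.impropers = {canonical_improper_key(*k): v for k, v in self.impropers.items()}
        for key, terms in self.dihedrals.items():
            ns = [t.n for t in terms]
            if len(ns) != len(set(ns)):
                raise ValueError(f"dihedral {key} carries more than one term per n")

    def penalty(self, key: tuple) -> float:
        return self.penalties.get(key, 0.0)

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            bonds=dict(self.bonds),
            angles=dict(self.angles),
            dihedrals={k: list(v) for k, v in self.dihedrals.items()},
            impropers=dict(self.impropers),
            nonbonded=dict(self.nonbonded),
            penalties=dict(self.penalties),
        )

    def set_dihedral_term(self, key: tuple[str, ...], term: DihedralTerm) -> None:
        """Insert/replace the term with matching n for `key` (canonicalised)."""
        key = canonical_dihedral_key(*key)
        terms = [t for t in self.dihedrals.get(key, []) if t.n != term.n]
        terms.append(term.canonical())
        terms.sort(key=lambda t: t.n)
        self.dihedrals[key] = terms


@dataclass
class Frame:
    """One geometry, optionally with an energy and driven-torsion record."""

    coordinates: np.ndarray
    energy: float | None = None
    driven_angles: dict[tuple[int, int, int, int], float] | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        if self.energy is not None and not math.isfinite(self.energy):
            raise ValueError("frame energy must be finite")


@dataclass
class MoleculeSystem:
    """Atoms, connectivity, and the reference (equilibrium) geometry.

    Angle instances are exactly the length-2 simple paths of the bond
    graph; dihedral instances exactly the length-3 simple paths.  Both are
    derived, not stored.
    """

    atoms: list[AtomSpec]
    bonds: frozenset[tuple[int, int]]
    reference_geometry: np.ndarray
    bond_orders: dict[tuple[int, int], int] | None = None
    impropers: list[tuple[int, int, int, int]] = field(default_factory=list)
    selections: dict[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.atoms)
        norm_bonds = set()
        for a, b in self.bonds:
            if a == b:
                raise ValueError(f"self-bond on atom {a}")
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"bond ({a},{b}) out of range for {n} atoms")
            norm_bonds.add((min(a, b), max(a, b)))
        self.bonds = frozenset(norm_bonds)
        if self.bond_orders is not None:
            self.bond_orders = {
                (min(a, b), max(a, b)): o for (a, b), o in self.bond_orders.items()
            }
        if len({a.index for a in self.atoms}) != n:
            raise ValueError("atom indices must be unique")
        self.reference_geometry = np.asarray(self.reference_geometry, dtype=float)
        if self.reference_geometry.shape != (n, 3):
            raise ValueError(
                f"reference geometry shape {self.reference_geometry.shape} "
                f"does not match {n} atoms"
            )
        if n > 1 and not self._connected():
            raise ValueError("bond graph is not connected")

    def _connected(self) -> bool:
        adj = self.adjacency
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(self.atoms)

    @cached_property
    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for a, b in sorted(self.bonds):
            adj[a].append(b)
            adj[b].append(a)
        return [sorted(x) for x in adj]

    @cached_property
    def angle_instances(self) -> list[tuple[int, int, int]]:
        out = []
        for j in range(len(self.atoms)):
            nbs = self.adjacency[j]
            for x in range(len(nbs)):
                for y in range(x + 1, len(nbs)):
                    out.append((nbs[x], j, nbs[y]))
        return out

    @cached_property
    def dihedral_instances(self) -> list[tuple[int, int, int, int]]:
        out = []
        for j, k in sorted(self.bonds):
            for i in self.adjacency[j]:
                if i == k:
                    continue
                for l in self.adjacency[k]:
                    if l == j or l == i:
                        continue
                    out.append((i, j, k, l))
        return out

    def atom_types(self) -> list[str]:
        return [a.atom_type for a in self.atoms]

    def bond_key(self, i: int, j: int) -> tuple[str, str]:
        t = self.atom_types()
        return canonical_bond_key(t[i], t[j])

    def angle_key(self, i: int, j: int, k: int) -> tuple[str, str, str]:
        t = self.atom_types()
        return canonical_angle_key(t[i], t[j], t[k])

    def dihedral_key(self, i: int, j: int, k: int, l: int) -> tuple[str, ...]:
        t = self.atom_types()
        return canonical_dihedral_key(t[i], t[j], t[k], t[l])

    def instances_of_dihedral_type(self, key: tuple[str, ...]):
        key = canonical_dihedral_key(*key)
        return [q for q in self.dihedral_instances if self.dihedral_key(*q) == key]

    @cached_property
    def exclusion_pairs(self) -> frozenset[tuple[int, int]]:
        """1-2 and 1-3 pairs, excluded from nonbonded."""
        excl = set(self.bonds)
        for i, j, k in self.angle_instances:
            excl.add((min(i, k), max(i, k)))
        return frozenset(excl)

    @cached_property
    def nonbonded_pairs(self) -> list[tuple[int, int]]:
        n = len(self.atoms)
        excl = self.exclusion_pairs
        return [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if (i, j) not in excl
        ]


# ---------------------------------------------------------------------------
# scalar geometry measurements
# ---------------------------------------------------------------------------

def measure_bond(geometry: np.ndarray, pair: Sequence[int]) -> float:
    geometry = np.asarray(geometry, dtype=float)
    i, j = pair
    return float(np.linalg.norm(geometry[j] - geometry[i]))


def measure_angle(geometry: np.ndarray, triple: Sequence[int]) -> float:
    """Valence angle i-j-k in degrees."""
    geometry = np.asarray(geometry, dtype=float)
    i, j, k = triple
    u = geometry[i] - geometry[j]
    v = geometry[k] - geometry[j]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-10 or nv < 1e-10:
        raise DegenerateGeometryError(f"coincident atoms in angle ({i},{j},{k})")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def measure_dihedral(geometry: np.ndarray, quadruple: Sequence[int]) -> float:
    """Signed torsion i-j-k-l in degrees, IUPAC convention, in (-180, 180].

    Reversing the quadruple returns the same value.  Raises
    DegenerateGeometryError when either bonded triple is collinear.
    """
    geometry = np.asarray(geometry, dtype=float)
    i, j, k, l = quadruple
    if len({i, j, k, l}) != 4:
        raise ValueError(f"dihedral indices must be distinct, got {(i, j, k, l)}")
    b1 = geometry[j] - geometry[i]
    b2 = geometry[k] - geometry[j]
    b3 = geometry[l] - geometry[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError(
            f"collinear atom triple in dihedral ({i},{j},{k},{l})"
        )
    b2n = np.linalg.norm(b2)
    y = np.dot(np.cross(n1, n2), b2) / b2n
    x = np.dot(n1, n2)
    phi = math.degrees(math.atan2(y, x))
    return wrap_angle_deg(phi)


def dihedral_term_energy(terms: Iterable[DihedralTerm], phi: float) -> float:
    """Sum of k*(1+cos(n*phi - delta)) over terms; phi in degrees."""
    phi_rad = math.radians(phi)
    total = 0.0
    for t in terms:
        total += t.k_phi * (1.0 + math.cos(t.n * phi_rad - math.radians(t.delta)))
    return total


# ---------------------------------------------------------------------------
# vectorised torsion values and gradients
# ---------------------------------------------------------------------------

def _torsion_values(coords: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Torsion angles in radians for an (m,4) index array, range (-pi, pi]."""
    i, j, k, l = quads.T
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / b2n
    x = np.einsum("ij,ij->i", n1, n2)
    return np.arctan2(y, x)


def _torsion_values_and_jacobians(coords: np.ndarray, quads: np.ndarray):
    """Torsions (rad) plus d(phi)/d(r) for each of the 4 atoms.

    Returns (phi[m], grads[m,4,3]); grads rows sum to zero (translation
    invariance).
    """
    i, j, k, l = quads.T
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / b2n
    x = np.einsum("ij,ij->i", n1, n2)
    phi = np.arctan2(y, x)

    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    b2nsq = b2n * b2n
    # Blondel-Karplus torsion derivatives
    dphi_di = -(b2n / n1sq)[:, None] * n1
    dphi_dl = (b2n / n2sq)[:, None] * n2
    t1 = (np.einsum("ij,ij->i", b1, b2) / b2nsq)[:, None]
    t3 = (np.einsum("ij,ij->i", b3, b2) / b2nsq)[:, None]
    dphi_dj = -dphi_di - t1 * dphi_di + t3 * dphi_dl
    dphi_dk = -dphi_dl + t1 * dphi_di - t3 * dphi_dl
    grads = np.stack([dphi_di, dphi_dj, dphi_dk, dphi_dl], axis=1)
    return phi, grads


def torsion_value_and_gradient(coords: np.ndarray, quad: Sequence[int]):
    """Scalar torsion (radians) and its (N,3) Cartesian gradient."""
    coords = np.asarray(coords, dtype=float)
    quads = np.asarray([quad], dtype=int)
    phi, grads = _torsion_values_and_jacobians(coords, quads)
    full = np.zeros_like(coords)
    for slot, atom in enumerate(quad):
        full[atom] += grads[0, slot]
    return float(phi[0]), full


def bond_value_and_gradient(coords: np.ndarray, pair: Sequence[int]):
    """Bond length (A) and its (N,3) gradient."""
    coords = np.asarray(coords, dtype=float)
    i, j = pair
    d = coords[j] - coords[i]
    r = float(np.linalg.norm(d))
    full = np.zeros_like(coords)
    u = d / r
    full[j] += u
    full[i] -= u
    return r, full


def angle_value_and_gradient(coords: np.ndarray, triple: Sequence[int]):
    """Valence angle (radians) and its (N,3) gradient."""
    coords = np.asarray(coords, dtype=float)
    i, j, k = triple
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    cos_t = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    theta = float(np.arccos(cos_t))
    sin_t = math.sqrt(max(1.0 - cos_t * cos_t, 1e-16))
    di = (cos_t * u / nu - v / nv) / (nu * sin_t)
    dk = (cos_t * v / nv - u / nu) / (nv * sin_t)
    full = np.zeros_like(coords)
    full[i] += di
    full[k] += dk
    full[j] -= di + dk
    return theta, full


# ---------------------------------------------------------------------------
# MM energy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnergyOptions:
    """Term-class toggles plus per-type dihedral zeroing."""

    bonds: bool = True
    angles: bool = True
    dihedrals: bool = True
    impropers: bool = True
    lj: bool = True
    coulomb: bool = True
    zeroed_dihedral_types: frozenset[tuple[str, ...]] = frozenset()

    def with_zeroed(self, keys: Iterable[tuple[str, ...]]) -> "EnergyOptions":
        zeroed = frozenset(canonical_dihedral_key(*k) for k in keys)
        return replace(self, zeroed_dihedral_types=zeroed)


@dataclass
class EnergyBreakdown:
    bond: float = 0.0
    angle: float = 0.0
    dihedral: float = 0.0
    improper: float = 0.0
    lj: float = 0.0
    coulomb: float = 0.0

    @property
    def total(self) -> float:
        return self.bond + self.angle + self.dihedral + self.improper + self.lj + self.coulomb

    def as_dict(self) -> dict[str, float]:
        return {
            "bond": self.bond, "angle": self.angle, "dihedral": self.dihedral,
            "improper": self.improper, "lj": self.lj, "coulomb": self.coulomb,
            "total": self.total,
        }


class MMEvaluator:
    """Precompiled evaluator of the bonded + nonbonded energy of one system.

    Construction resolves every instance to a parameter (canonical key
    orientation) and fails loudly on a missing one.
    """

    def __init__(self, system: MoleculeSystem, params: ParameterSet,
                 options: EnergyOptions = EnergyOptions()):
        self.system = system
        self.params = params
        self.options = options
        t = system.atom_types()

        # bonds
        bidx, bk, bb0 = [], [], []
        if options.bonds:
            for i, j in sorted(system.bonds):
                key = canonical_bond_key(t[i], t[j])
                if key not in params.bonds:
                    raise UnparametrisedInstanceError(f"no bond parameter for {key}")
                p = params.bonds[key]
                bidx.append((i, j)); bk.append(p.k_b); bb0.append(p.b0)
        self._bidx = np.asarray(bidx, dtype=int).reshape(-1, 2)
        self._bk = np.asarray(bk, dtype=float)
        self._bb0 = np.asarray(bb0, dtype=float)

        # angles
        aidx, ak, at0 = [], [], []
        if options.angles:
            for i, j, k in system.angle_instances:
                key = canonical_angle_key(t[i], t[j], t[k])
                if key not in params.angles:
                    raise UnparametrisedInstanceError(f"no angle parameter for {key}")
                p = params.angles[key]
                aidx.append((i, j, k)); ak.append(p.k_theta); at0.append(math.radians(p.theta0))
        self._aidx = np.asarray(aidx, dtype=int).reshape(-1, 3)
        self._ak = np.asarray(ak, dtype=float)
        self._at0 = np.asarray(at0, dtype=float)

        # dihedral cosine terms, flattened over (instance, term)
        didx, dk, dn, dd = [], [], [], []
        if options.dihedrals:
            zeroed = options.zeroed_dihedral_types
            for q in system.dihedral_instances:
                key = canonical_dihedral_key(*(t[x] for x in q))
                if key not in params.dihedrals:
                    raise UnparametrisedInstanceError(f"no dihedral parameter for {key}")
                if key in zeroed:
                    continue
                for term in params.dihedrals[key]:
                    didx.append(q)
                    dk.append(term.k_phi)
                    dn.append(term.n)
                    dd.append(math.radians(term.delta))
        self._didx = np.asarray(didx, dtype=int).reshape(-1, 4)
        self._dk = np.asarray(dk, dtype=float)
        self._dn = np.asarray(dn, dtype=float)
        self._dd = np.asarray(dd, dtype=float)

        # impropers: harmonic in the torsion measured on the stored order
        iidx, ik, iw0 = [], [], []
        if options.impropers:
            for q in system.impropers:
                key = canonical_improper_key(*(t[x] for x in q))
                if key not in params.impropers:
                    raise UnparametrisedInstanceError(f"no improper parameter for {key}")
                p = params.impropers[key]
                iidx.append(q); ik.append(p.k_omega); iw0.append(math.radians(p.omega0))
        self._iidx = np.asarray(iidx, dtype=int).reshape(-1, 4)
        self._ik = np.asarray(ik, dtype=float)
        self._iw0 = np.asarray(iw0, dtype=float)

        # nonbonded pairs
        pidx, qq, eps, rmin = [], [], [], []
        if options.lj or options.coulomb:
            for i, j in system.nonbonded_pairs:
                pidx.append((i, j))
                qq.append(system.atoms[i].charge * system.atoms[j].charge)
                ti, tj = t[i], t[j]
                if ti not in params.nonbonded or tj not in params.nonbonded:
                    missing = ti if ti not in params.nonbonded else tj
                    raise UnparametrisedInstanceError(f"no nonbonded parameter for type {missing}")
                ei, ri = params.nonbonded[ti]
                ej, rj = params.nonbonded[tj]
                eps.append(math.sqrt(ei * ej))
                rmin.append(ri + rj)
        self._pidx = np.asarray(pidx, dtype=int).reshape(-1, 2)
        self._qq = np.asarray(qq, dtype=float)
        self._eps = np.asarray(eps, dtype=float)
        self._rmin = np.asarray(rmin, dtype=float)

        self.n_atoms = len(system.atoms)

    # -- energy --------------------------------------------------------

    def energy(self, coords: np.ndarray) -> EnergyBreakdown:
        coords = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        out = EnergyBreakdown()
        o = self.options
        if o.bonds and len(self._bidx):
            d = coords[self._bidx[:, 1]] - coords[self._bidx[:, 0]]
            r = np.linalg.norm(d, axis=1)
            out.bond = float(np.sum(self._bk * (r - self._bb0) ** 2))
        if o.angles and len(self._aidx):
            theta = self._angle_values(coords)
            out.angle = float(np.sum(self._ak * (theta - self._at0) ** 2))
        if o.dihedrals and len(self._didx):
            phi = _torsion_values(coords, self._didx)
            out.dihedral = float(np.sum(self._dk * (1.0 + np.cos(self._dn * phi - self._dd))))
        if o.impropers and len(self._iidx):
            w = _torsion_values(coords, self._iidx)
            dw = np.arctan2(np.sin(w - self._iw0), np.cos(w - self._iw0))
            out.improper = float(np.sum(self._ik * dw ** 2))
        if (o.lj or o.coulomb) and len(self._pidx):
            d = coords[self._pidx[:, 1]] - coords[self._pidx[:, 0]]
            r = np.linalg.norm(d, axis=1)
            if o.lj:
                x = (self._rmin / r) ** 6
                out.lj = float(np.sum(self._eps * (x * x - 2.0 * x)))
            if o.coulomb:
                out.coulomb = float(np.sum(COULOMB_KCAL * self._qq / r))
        return out

    def _angle_values(self, coords: np.ndarray) -> np.ndarray:
        i, j, k = self._aidx.T
        u = coords[i] - coords[j]
        v = coords[k] - coords[j]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        c = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
        return np.arccos(c)

    # -- energy + gradient ---------------------------------------------

    def energy_and_gradient(self, coords: np.ndarray):
        """Total energy (kcal/mol) and gradient (N,3) (kcal/mol/A)."""
        coords = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        grad = np.zeros_like(coords)
        total = 0.0
        o = self.options

        if o.bonds and len(self._bidx):
            i, j = self._bidx.T
            d = coords[j] - coords[i]
            r = np.linalg.norm(d, axis=1)
            dr = r - self._bb0
            total += float(np.sum(self._bk * dr ** 2))
            f = (2.0 * self._bk * dr / r)[:, None] * d
            np.add.at(grad, j, f)
            np.add.at(grad, i, -f)

        if o.angles and len(self._aidx):
            i, j, k = self._aidx.T
            u = coords[i] - coords[j]
            v = coords[k] - coords[j]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            c = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
            theta = np.arccos(c)
            s = np.sqrt(np.clip(1.0 - c * c, 1e-16, None))
            dtheta = theta - self._at0
            total += float(np.sum(self._ak * dtheta ** 2))
            pref = 2.0 * self._ak * dtheta
            di = (c[:, None] * u / nu[:, None] - v / nv[:, None]) / (nu * s)[:, None]
            dk_ = (c[:, None] * v / nv[:, None] - u / nu[:, None]) / (nv * s)[:, None]
            np.add.at(grad, i, pref[:, None] * di)
            np.add.at(grad, k, pref[:, None] * dk_)
            np.add.at(grad, j, -pref[:, None] * (di + dk_))

        if o.dihedrals and len(self._didx):
            phi, dgr = _torsion_values_and_jacobians(coords, self._didx)
            arg = self._dn * phi - self._dd
            total += float(np.sum(self._dk * (1.0 + np.cos(arg))))
            dV = -self._dk * self._dn * np.sin(arg)
            for slot in range(4):
                np.add.at(grad, self._didx[:, slot], dV[:, None] * dgr[:, slot])

        if o.impropers and len(self._iidx):
            w, dgr = _torsion_values_and_jacobians(coords, self._iidx)
            dw = np.arctan2(np.sin(w - self._iw0), np.cos(w - self._iw0))
            total += float(np.sum(self._ik * dw ** 2))
            dV = 2.0 * self._ik * dw
            for slot in range(4):
                np.add.at(grad, self._iidx[:, slot], dV[:, None] * dgr[:, slot])

        if (o.lj or o.coulomb) and len(self._pidx):
            i, j = self._pidx.T
            d = coords[j] - coords[i]
            r = np.linalg.norm(d, axis=1)
            dEdr = np.zeros_like(r)
            if o.lj:
                x = (self._rmin / r) ** 6
                total += float(np.sum(self._eps * (x * x - 2.0 * x)))
                dEdr += self._eps * (-12.0 * x * x + 12.0 * x) / r
            if o.coulomb:
                ec = COULOMB_KCAL * self._qq / r
                total += float(np.sum(ec))
                dEdr += -ec / r
            f = (dEdr / r)[:, None] * d
            np.add.at(grad, j, f)
            np.add.at(grad, i, -f)

        return total, grad


def mm_energy(system: MoleculeSystem, params: ParameterSet, frame: Frame,
              options: EnergyOptions = EnergyOptions()) -> EnergyBreakdown:
    """Energy breakdown of one frame.  See MMEvaluator for term conventions."""
    return MMEvaluator(system, params, options).energy(frame.coordinates)


# ---------------------------------------------------------------------------
# rigid superposition
# ---------------------------------------------------------------------------

def kabsch_rmsd(reference: np.ndarray, mobile: np.ndarray,
                selection: Iterable[int] | None = None) -> float:
    """Minimum RMSD (A) over rigid superpositions of the selected atoms.

    Proper rotations only (no reflection); symmetric in its arguments.
    """
    reference = np.asarray(reference, dtype=float).reshape(-1, 3)
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    if selection is None:
        sel = np.arange(len(reference))
    else:
        sel = np.asarray(sorted(selection), dtype=int)
    if len(sel) < 3:
        raise UnderdeterminedSuperpositionError(
            f"selection of {len(sel)} atoms cannot define a superposition"
        )
    p = reference[sel] - reference[sel].mean(axis=0)
    q = mobile[sel] - mobile[sel].mean(axis=0)
    h = q.T @ p
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u @ vt))
    s_corr = np.array([1.0, 1.0, sign])
    # RMSD^2 = (|P|^2 + |Q|^2 - 2*sum(sigma_i * s_i)) / n
    msd = (np.sum(p * p) + np.sum(q * q) - 2.0 * np.sum(s * s_corr)) / len(sel)
    return float(math.sqrt(max(msd, 0.0)))


# ---------------------------------------------------------------------------
# Cartesian minimisation (shared by validation + synthetic)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TorsionRestraint:
    """Harmonic, periodicity-aware restraint k*(wrap(phi - target))^2."""

    quadruple: tuple[int, int, int, int]
    target_deg: float
    k: float = 1000.0  # kcal/mol/rad^2


def minimize_frame(evaluator: MMEvaluator, coords: np.ndarray,
                   restraints: Sequence[TorsionRestraint] = (),
                   gtol: float = 1e-6, maxiter: int = 5000):
    """Locally minimise the MM energy (plus optional torsion restraints).

    Returns (coords, energy_without_restraints, converged, max_grad) where
    max_grad is the largest unrestrained-gradient component at the
    solution when no restraints are active, else of the restrained
    objective.
    """
    from scipy.optimize import minimize as _sp_minimize

    n = evaluator.n_atoms
    targets = [math.radians(r.target_deg) for r in restraints]

    def objective(x):
        c = x.reshape(n, 3)
        e, g = evaluator.energy_and_gradient(c)
        for r, t in zip(restraints, targets):
            phi, dphi = torsion_value_and_gradient(c, r.quadruple)
            d = math.atan2(math.sin(phi - t), math.cos(phi - t))
            e += r.k * d * d
            g += 2.0 * r.k * d * dphi
        return e, g.ravel()

    def newton_polish(x, iters=12, step_cap=0.5):
        # L-BFGS stalls both near machine precision and in stiff, narrow
        # restrained-ring valleys; damped Newton steps with a finite-
        # difference Hessian (rigid modes projected out via pinv, step
        # length capped) handle both on these small systems.
        dim = x.size
        h = 1e-5
        for _ in range(iters):
            _, g = objective(x)
            if np.max(np.abs(g)) < gtol:
                break
            hess = np.empty((dim, dim))
            for m in range(dim):
                xp = x.copy(); xp[m] += h
                xm = x.copy(); xm[m] -= h
                hess[:, m] = (objective(xp)[1] - objective(xm)[1]) / (2 * h)
            hess = 0.5 * (hess + hess.T)
            step = np.linalg.pinv(hess, rcond=1e-8) @ g
            norm = np.linalg.norm(step)
            if norm > step_cap:
                step *= step_cap / norm
            e0, _ = objective(x)
            scale = 1.0
            improved = False
            for _ls in range(25):
                e1, _ = objective(x - scale * step)
                if e1 <= e0 + 1e-12:
                    x = x - scale * step
                    improved = True
                    break
                scale *= 0.5
            if not improved:
                # fall back to steepest descent with line search
                d = g / max(np.linalg.norm(g), 1e-12)
                scale = 0.1
                for _ls in range(30):
                    e1, _ = objective(x - scale * d)
                    if e1 < e0:
                        x = x - scale * d
                        improved = True
                        break
                    scale *= 0.5
                if not improved:
                    break
        return x

    x = np.asarray(coords, dtype=float).ravel().copy()
    converged = False
    max_g = np.inf
    for attempt in range(8):
        res = _sp_minimize(objective, x, jac=True, method="L-BFGS-B",
                           options={"maxiter": maxiter, "ftol": 1e-15,
                                    "gtol": max(gtol * 0.3, 1e-12), "maxcor": 30})
        x = res.x
        _, g = objective(x)
        max_g = float(np.max(np.abs(g)))
        if max_g < gtol:
            converged = True
            break
        if max_g < 1e-3 or attempt >= 2:
            x = newton_polish(x, iters=12 if max_g < 1e-3 else 30)
            _, g = objective(x)
            max_g = float(np.max(np.abs(g)))
            if max_g < gtol:
                converged = True
                break
    final = x.reshape(n, 3)
    energy = evaluator.energy(final).total
    return final, energy, converged, max_g
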