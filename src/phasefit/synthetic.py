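"""Synthetic fused-ring fixtures with known ground-truth parameters.

Fixtures are MM-native: the "target" (QM-like) data handed to the fitting
stages is generated from a ground-truth MM parameter set, so parameter
recovery is exact in the noiseless limit and protocol correctness can be
tested separately from any QM/MM model error.

``make_fixture`` guarantees that the reference geometry is a strict local
minimum of the ground-truth energy (max gradient component < 1e-6) and
that the geometry-based phase prediction reproduces the ground-truth
phase shift for every non-ambiguous term (the construction loop flips
and re-minimises until self-consistent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    AngleParam,
    AtomSpec,
    BondParam,
    DihedralTerm,
    ImproperParam,
    MMEvaluator,
    MoleculeSystem,
    ParameterSet,
    TorsionRestraint,
    canonical_dihedral_key,
    measure_angle,
    measure_bond,
    measure_dihedral,
    minimize_frame,
)
from .dihedrals import DihedralGroup
from .errors import MinimisationError, RingTorsionError
from .formats import HessianMatrix, ScanTable
from .synthetic_geometry import downstream_atoms, rotate_fragment

TEMPLATES = ("chain", "ring4", "ring5", "fused45", "fused46", "fused45-carboxylate")


@dataclass(frozen=True)
class FixtureSpec:
    template: str = "fused45"
    seed: int = 0
    noise_sigma: float = 0.0
    flip_mode: bool = False
    perturb_params: bool = False
    perturb_scope: str = "all"  # "all" | "dihedral-only"
    # single cosine term per dihedral type; keeps every force constant
    # well-identified on a cutoff-limited scan window (multi-term types can
    # sit in a flat objective direction, which fit_group surfaces via its
    # condition number instead)
    simple_terms: bool = False

    def __post_init__(self):
        if self.template not in TEMPLATES:
            raise ValueError(f"unknown template {self.template!r}")
        if self.flip_mode and self.template != "fused45":
            raise ValueError("flip_mode is implemented for the fused45 template")
        if self.perturb_scope not in ("all", "dihedral-only"):
            raise ValueError(f"unknown perturb_scope {self.perturb_scope!r}")


@dataclass
class Fixture:
    spec: FixtureSpec
    system: MoleculeSystem
    true_params: ParameterSet
    start_params: ParameterSet
    rings: list[frozenset[int]]
    rotatable: list[tuple[int, int, int, int]]
    flip_pair: tuple | None
    ambiguous_terms: set[tuple]
    carboxylate_atoms: frozenset[int] = frozenset()
    carboxylate_terminal_type: str | None = None

    def default_groups(self) -> list[DihedralGroup]:
        """Group dihedral types by the ring membership of the central bond.

        Double-bond types rank first, then 4-ring, then the fused 5/6
        ring, then open-chain types; carboxylate types come last —
        mirroring the group-sequential protocol.
        """
        types = self.system.atom_types()
        ring4 = next((r for r in self.rings if len(r) == 4), frozenset())
        big_ring = next((r for r in self.rings if len(r) in (5, 6)), frozenset())
        buckets: dict[str, set] = {"double-bond": set(), "ring4": set(),
                                   "fused": set(), "chain": set(),
                                   "carboxylate": set()}
        orders = self.system.bond_orders or {}
        for (i, j, k, l) in self.system.dihedral_instances:
            key = canonical_dihedral_key(*(types[x] for x in (i, j, k, l)))
            bond = (min(j, k), max(j, k))
            if {j, k, l} & self.carboxylate_atoms or {i, j, k} & self.carboxylate_atoms:
                buckets["carboxylate"].add(key)
            elif orders.get(bond, 1) == 2:
                buckets["double-bond"].add(key)
            elif j in ring4 and k in ring4:
                buckets["ring4"].add(key)
            elif j in big_ring and k in big_ring:
                buckets["fused"].add(key)
            else:
                buckets["chain"].add(key)
        # a type may straddle buckets only via distinct instances of the
        # same key; keep the highest-priority assignment and drop overlaps
        rank = {"double-bond": 0, "ring4": 1, "fused": 2, "chain": 3,
                "carboxylate": 4}
        taken: set = set()
        groups = []
        for name in sorted(buckets, key=lambda n: rank[n]):
            members = buckets[name] - taken
            taken |= members
            if members:
                groups.append(DihedralGroup(name, frozenset(members), rank[name]))
        return groups


# ---------------------------------------------------------------------------
# template topologies (rough coordinates; minimisation does the rest)
# ---------------------------------------------------------------------------

def _zigzag(n, bond=1.5, angle=111.0):
    half = math.radians(angle) / 2.0
    dx = bond * math.sin(half)
    dy = bond * math.cos(half)
    return np.array([[i * dx, (i % 2) * dy, 0.02 * i] for i in range(n)])


def _polygon(n, side=1.5, z=0.0):
    r = side / (2.0 * math.sin(math.pi / n))
    return np.array([
        [r * math.cos(2 * math.pi * i / n), r * math.sin(2 * math.pi * i / n), z]
        for i in range(n)
    ])


def _template(name: str, flip: bool = False):
    """-> (types, elements, coords, bonds, bond_orders, impropers, meta)."""
    if name == "chain":
        n = 6
        types = [f"CH{i+1}" for i in range(n)]
        elems = ["C"] * n
        coords = _zigzag(n)
        bonds = {(i, i + 1) for i in range(n - 1)}
        return types, elems, coords, bonds, {}, [], {"rings": []}

    if name == "ring4":
        types = ["R4A", "R4B", "R4C", "R4D", "S4A", "S4B"]
        elems = ["C", "C", "C", "N", "C", "C"]
        ring = _polygon(4, side=1.52)
        subs = np.array([[2.6, 0.0, 0.4], [-2.6, 0.0, -0.4]])
        coords = np.vstack([ring, subs])
        bonds = {(0, 1), (1, 2), (2, 3), (3, 0), (0, 4), (2, 5)}
        return types, elems, coords, bonds, {}, [], {"rings": [frozenset({0, 1, 2, 3})]}

    if name == "ring5":
        types = ["R5A", "R5B", "R5C", "R5D", "R5E", "S5A"]
        elems = ["C", "C", "C", "C", "S", "C"]
        ring = _polygon(5, side=1.5)
        coords = np.vstack([ring, [[2.9, 0.0, 0.5]]])
        bonds = {(0, 1), (1, 2), (2, 3), (3, 4), (4, 0), (0, 5)}
        return types, elems, coords, bonds, {}, [], {"rings": [frozenset(range(5))]}

    if name in ("fused45", "fused45-carboxylate"):
        # 4-ring {0,1,2,3} fused to 5-ring {0,3,4,5,6} along edge 0-3
        types = ["F5A", "F5B", "F5C", "F5N", "F5S", "F5E", "F5F", "F5G"]
        elems = ["C", "C", "C", "N", "S", "C", "C", "C"]
        coords = np.array([
            [0.0, 0.76, 0.00],
            [-1.5, 0.76, 0.15],
            [-1.5, -0.76, -0.15],
            [0.0, -0.76, 0.05],
            [1.25, -1.35, 0.10],
            [2.25, -0.05, -0.12],
            [1.25, 1.30, 0.08],
            [-2.7, 1.60, 0.00],
        ])
        bonds = {(0, 1), (1, 2), (2, 3), (3, 0),
                 (3, 4), (4, 5), (5, 6), (6, 0), (1, 7)}
        meta = {"rings": [frozenset({0, 1, 2, 3}), frozenset({0, 3, 4, 5, 6})]}
        if name == "fused45":
            if flip:
                # no exocyclic substituent: everything except the 5-ring
                # apex stays (near-)planar, so the flipped pucker is the
                # molecule's near-exact mirror image and almost degenerate
                return (types[:7], elems[:7], coords[:7],
                        bonds - {(1, 7)}, {}, [], meta)
            return types, elems, coords, bonds, {}, [], meta
        # append a carboxylate (two equivalent oxygens) on atom 5
        types = types + ["CCX", "OCX", "OCX"]
        elems = elems + ["C", "O", "O"]
        carbox = np.array([
            [3.75, -0.05, -0.20],
            [4.40, -1.10, -0.35],
            [4.40, 1.00, -0.10],
        ])
        coords = np.vstack([coords, carbox])
        bonds = bonds | {(5, 8), (8, 9), (8, 10)}
        impropers = [(8, 5, 9, 10)]
        meta = dict(meta)
        meta["carboxylate"] = frozenset({8, 9, 10})
        meta["carboxylate_terminal_type"] = "OCX"
        return types, elems, coords, bonds, {}, impropers, meta

    if name == "fused46":
        # 4-ring {0,1,2,3} fused to 6-ring {0,3,4,5,6,7}; double bond 5-6
        types = ["F6A", "F6B", "F6C", "F6N", "F6D", "F6E", "F6F", "F6G", "F6H"]
        elems = ["C", "C", "C", "N", "C", "C", "C", "C", "C"]
        coords = np.array([
            [0.0, 0.76, 0.00],
            [-1.5, 0.76, 0.15],
            [-1.5, -0.76, -0.15],
            [0.0, -0.76, 0.05],
            [1.30, -1.50, 0.10],
            [2.60, -0.76, -0.10],
            [2.60, 0.76, 0.10],
            [1.30, 1.50, -0.08],
            [-2.7, 1.60, 0.00],
        ])
        bonds = {(0, 1), (1, 2), (2, 3), (3, 0),
                 (3, 4), (4, 5), (5, 6), (6, 7), (7, 0), (1, 8)}
        orders = {(5, 6): 2}
        meta = {"rings": [frozenset({0, 1, 2, 3}), frozenset({0, 3, 4, 5, 6, 7})]}
        return types, elems, coords, bonds, orders, [], meta

    raise ValueError(name)


# ---------------------------------------------------------------------------
# fixture construction
# ---------------------------------------------------------------------------

def make_fixture(spec: FixtureSpec) -> Fixture:
    rng = np.random.default_rng(spec.seed)
    types, elems, coords, bonds, orders, impropers, meta = _template(
        spec.template, flip=spec.flip_mode)
    n = len(types)

    charges = rng.uniform(-0.12, 0.12, size=n)
    charges -= charges.mean()

    atoms = [AtomSpec(i, elems[i], types[i], float(charges[i]),
                      12.011 if elems[i] == "C" else 15.0, name=f"A{i+1}")
             for i in range(n)]

    system = MoleculeSystem(
        atoms=atoms, bonds=frozenset(bonds), reference_geometry=coords,
        bond_orders=orders or None, impropers=list(impropers),
    )

    params = ParameterSet()
    for t in sorted(set(types)):
        if spec.flip_mode and t in (types[0], types[5]):
            params.nonbonded[t] = (0.15, 2.1)
        else:
            params.nonbonded[t] = (float(rng.uniform(0.05, 0.12)),
                                   float(rng.uniform(1.7, 2.0)))

    # equilibrium values near the template geometry keep the minimiser local
    for i, j in sorted(system.bonds):
        key = system.bond_key(i, j)
        if key not in params.bonds:
            b0 = measure_bond(coords, (i, j)) + float(rng.uniform(-0.02, 0.02))
            params.bonds[key] = BondParam(float(rng.uniform(250.0, 350.0)), b0)
    ring4_atoms = next((r for r in meta.get("rings", []) if len(r) == 4), frozenset())
    ring5_atoms = next((r for r in meta.get("rings", []) if len(r) == 5), frozenset())
    for tri in system.angle_instances:
        key = system.angle_key(*tri)
        if key not in params.angles:
            if spec.flip_mode and set(tri) <= ring5_atoms and not set(tri) <= ring4_atoms:
                # slightly pinched, soft 5-ring angles force a pucker with
                # two mirror-image (up/down) envelope conformers
                params.angles[key] = AngleParam(22.0, float(rng.uniform(99.0, 101.0)))
            elif spec.flip_mode and set(tri) <= ring4_atoms:
                params.angles[key] = AngleParam(120.0, 89.5)
            else:
                t0 = measure_angle(coords, tri) + float(rng.uniform(-2.0, 2.0))
                t0 = min(max(t0, 30.0), 175.0)
                params.angles[key] = AngleParam(float(rng.uniform(60.0, 100.0)), t0)
    for q in impropers:
        key = canonical_dihedral_key(*(types[x] for x in q))
        params.impropers[key] = ImproperParam(float(rng.uniform(30.0, 60.0)), 0.0)

    # placeholder zero-k dihedral terms so the base minimisation is defined
    dihedral_keys = sorted({system.dihedral_key(*q) for q in system.dihedral_instances})
    for key in dihedral_keys:
        params.dihedrals[key] = [DihedralTerm(0.0, 3, 0.0)]

    ev0 = MMEvaluator(system, params)
    base, _e, conv, mg = minimize_frame(ev0, coords, gtol=1e-6)
    if not conv:
        raise MinimisationError(f"base minimisation stalled (max grad {mg:.2e})")
    system = _with_geometry(system, base)

    flip_pair = None
    flip_keys: set = set()
    if spec.flip_mode:
        # two adjacent 5-ring torsions whose concerted rotation carries the
        # ring between its mirror-image envelope conformers
        flip_pair = ((0, 3, 4, 5), (3, 4, 5, 6))
        soft_bonds = {(3, 4), (4, 5), (5, 6), (0, 6)}
        for q in system.dihedral_instances:
            if (min(q[1], q[2]), max(q[1], q[2])) in soft_bonds:
                flip_keys.add(system.dihedral_key(*q))

    _assign_true_dihedrals(system, params, rng, spec, flip_keys)

    # self-consistency loop: minimise, re-predict phases, flip disagreements
    geometry = system.reference_geometry
    ambiguous: set[tuple] = set()
    ev = MMEvaluator(system, params)
    for _round in range(6):
        geometry, _e, conv, mg = minimize_frame(ev, geometry, gtol=1e-6)
        if not conv:
            raise MinimisationError(f"fixture minimisation stalled (max grad {mg:.2e})")
        system = _with_geometry(system, geometry)
        ambiguous = set()
        flips = 0
        for key in dihedral_keys:
            instances = system.instances_of_dihedral_type(key)
            phi0s = [measure_dihedral(geometry, q) for q in instances]
            for term in list(params.dihedrals[key]):
                s0 = sum(math.cos(math.radians(term.n * p)) for p in phi0s)
                s180 = -s0
                gap = abs(s0 - s180)
                predicted = 0.0 if s0 < s180 else 180.0
                if gap < 0.05 * len(phi0s):
                    ambiguous.add((key, term.n))
                elif term.k_phi > 0 and predicted != term.delta:
                    params.set_dihedral_term(key, DihedralTerm(term.k_phi, term.n, predicted))
                    flips += 1
        if flips == 0:
            break
        ev = MMEvaluator(system, params)
    else:
        raise MinimisationError("phase self-consistency loop did not settle")

    system = _finalise_selections(system, meta)
    start = _corrupt_params(params, rng, spec) if spec.perturb_params else params.copy()

    rotatable = _rotatable_torsions(system)
    return Fixture(
        spec=spec, system=system, true_params=params, start_params=start,
        rings=list(meta.get("rings", [])), rotatable=rotatable,
        flip_pair=flip_pair, ambiguous_terms=ambiguous,
        carboxylate_atoms=frozenset(meta.get("carboxylate", frozenset())),
        carboxylate_terminal_type=meta.get("carboxylate_terminal_type"),
    )


def _with_geometry(system: MoleculeSystem, geometry) -> MoleculeSystem:
    return MoleculeSystem(
        atoms=system.atoms, bonds=system.bonds,
        reference_geometry=np.asarray(geometry, dtype=float),
        bond_orders=system.bond_orders, impropers=system.impropers,
        selections=dict(system.selections),
    )


def _assign_true_dihedrals(system, params, rng, spec, flip_keys=frozenset()):
    """Sample ground-truth terms; phases predicted from the base geometry."""
    geometry = system.reference_geometry

    for key in sorted(params.dihedrals):
        if key in flip_keys:
            # weak ring torsions keep the pucker flip nearly barrierless
            instances = system.instances_of_dihedral_type(key)
            phi0s = [measure_dihedral(geometry, q) for q in instances]
            s0 = sum(math.cos(math.radians(2 * p)) for p in phi0s)
            params.dihedrals[key] = [DihedralTerm(0.15, 2, 0.0 if s0 < 0 else 180.0)]
            continue
        instances = system.instances_of_dihedral_type(key)
        phi0s = [measure_dihedral(geometry, q) for q in instances]
        candidates = [1, 2, 3]
        rng.shuffle(candidates)
        chosen = None
        for cn in candidates:
            s0 = sum(math.cos(math.radians(cn * p)) for p in phi0s)
            if abs(2 * s0) >= 0.3 * len(phi0s):
                chosen = cn
                break
        if chosen is None:
            chosen = candidates[0]
        s0 = sum(math.cos(math.radians(chosen * p)) for p in phi0s)
        delta = 0.0 if s0 < 0 else 180.0
        central_in_ring = _central_bond_in_ring(system, instances[0])
        k_hi = 0.9 if central_in_ring else 1.8
        k = float(rng.uniform(0.25, k_hi))
        params.dihedrals[key] = [DihedralTerm(k, chosen, delta)]
        if not central_in_ring and not spec.simple_terms and rng.random() < 0.35:
            extra_n = next((m for m in (1, 2, 3) if m != chosen), 1)
            s0x = sum(math.cos(math.radians(extra_n * p)) for p in phi0s)
            if abs(2 * s0x) >= 0.3 * len(phi0s):
                dx = 0.0 if s0x < 0 else 180.0
                params.dihedrals[key].append(
                    DihedralTerm(float(rng.uniform(0.2, 0.8)), extra_n, dx))
                params.dihedrals[key].sort(key=lambda t: t.n)

    orders = system.bond_orders or {}
    for key in sorted(params.dihedrals):
        # double bonds are stiff: big k, n=2, delta=180
        for q in system.instances_of_dihedral_type(key):
            bond = (min(q[1], q[2]), max(q[1], q[2]))
            if orders.get(bond, 1) == 2:
                params.dihedrals[key] = [DihedralTerm(float(rng.uniform(8.0, 12.0)), 2, 180.0)]
                break


def _central_bond_in_ring(system, quad) -> bool:
    try:
        downstream_atoms(system, quad[1], quad[2])
    except RingTorsionError:
        return True
    return False


def _rotatable_torsions(system) -> list[tuple[int, int, int, int]]:
    """One representative non-ring torsion per rotatable central bond."""
    seen_bonds = set()
    out = []
    for q in system.dihedral_instances:
        bond = (min(q[1], q[2]), max(q[1], q[2]))
        if bond in seen_bonds:
            continue
        if not _central_bond_in_ring(system, q):
            seen_bonds.add(bond)
            out.append(q)
    return out


def _finalise_selections(system, meta) -> MoleculeSystem:
    heavy = frozenset(i for i, a in enumerate(system.atoms) if a.element.upper() != "H")
    carbox = frozenset(meta.get("carboxylate", frozenset()))
    rings = meta.get("rings", [])
    ring_atoms = frozenset().union(*rings) if rings else heavy
    selections = {
        "heavy": heavy,
        "ring-heavy": frozenset((ring_atoms & heavy) - carbox),
    }
    return MoleculeSystem(
        atoms=system.atoms, bonds=system.bonds,
        reference_geometry=system.reference_geometry,
        bond_orders=system.bond_orders, impropers=system.impropers,
        selections=selections,
    )


def _corrupt_params(params: ParameterSet, rng, spec: FixtureSpec) -> ParameterSet:
    """CGenFF-like starting guess: biased angles, randomised dihedrals.

    Corrupted entries carry penalties > 10; untouched entries penalty 0.
    """
    out = params.copy()
    out.penalties = {}
    for key, terms in sorted(out.dihedrals.items()):
        new_terms = []
        for t in terms:
            k = float(t.k_phi * rng.uniform(0.3, 1.8) + rng.uniform(0.0, 0.3))
            delta = 180.0 - t.delta if rng.random() < 0.5 else t.delta
            new_terms.append(DihedralTerm(k, t.n, delta))
        out.dihedrals[key] = new_terms
        out.penalties[key] = float(rng.uniform(15.0, 60.0))
    if spec.perturb_scope == "all":
        for key in sorted(out.angles):
            if rng.random() < 0.6:
                p = out.angles[key]
                t0 = min(max(p.theta0 + float(rng.uniform(-20.0, 20.0)), 30.0), 175.0)
                out.angles[key] = AngleParam(p.k_theta * float(rng.uniform(0.5, 1.5)), t0)
                out.penalties[key] = float(rng.uniform(15.0, 60.0))
        for key in sorted(out.bonds):
            if rng.random() < 0.4:
                p = out.bonds[key]
                out.bonds[key] = BondParam(p.k_b * float(rng.uniform(0.7, 1.3)),
                                           p.b0 + float(rng.uniform(-0.04, 0.04)))
                out.penalties[key] = float(rng.uniform(15.0, 60.0))
    return out


# ---------------------------------------------------------------------------
# scan + Hessian generation
# ---------------------------------------------------------------------------

def generate_scan(fixture: Fixture, driven, scan_range=(-90.0, 90.0),
                  step: float = 10.0, mode: str = "relaxed",
                  noise_sigma: float = 0.0, seed: int = 0,
                  restraint_k: float = 1000.0, center: str = "reference") -> ScanTable:
    """Drive one or two torsions and record ground-truth energies.

    Rigid mode rotates the downstream fragment (errors on ring-internal
    torsions); relaxed mode minimises everything else under a stiff
    harmonic restraint on the driven torsion(s).  Offsets are taken
    relative to the reference-geometry torsion; declared angles are the
    (unwrapped) targets.  Energies are ground-truth MM plus Gaussian
    noise; the exact per-row decomposition is kept in ``ScanTable.truth``.
    """
    if isinstance(driven[0], int):
        driven = (tuple(driven),)
    driven = tuple(tuple(q) for q in driven)
    lo, hi = scan_range
    n_steps = (hi - lo) / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("step must divide the scan range")
    offsets = lo + step * np.arange(int(round(n_steps)) + 1)

    system = fixture.system
    ev = MMEvaluator(system, fixture.true_params)
    rng = np.random.default_rng(seed)
    ref = system.reference_geometry
    if center == "reference":
        phi0 = [measure_dihedral(ref, q) for q in driven]
    elif center == "zero":
        phi0 = [0.0 for _ in driven]
    else:
        raise ValueError(f"unknown scan center {center!r}")

    if len(driven) == 1:
        rows = [(o,) for o in offsets]
    else:
        rows = [(o1, o2) for o1 in offsets for o2 in offsets]  # row-major

    frames, angles, energies, breakdowns = [], [], [], []
    if mode == "rigid":
        for q in driven:
            downstream_atoms(system, q[1], q[2])  # raises inside rings
        for row in rows:
            coords = ref.copy()
            for d, off in enumerate(row):
                coords = rotate_fragment(system, coords, driven[d],
                                         phi0[d] + off, relative=False)
            frames.append(coords)
            angles.append([phi0[d] + off for d, off in enumerate(row)])
            bd = ev.energy(coords)
            energies.append(bd.total)
            breakdowns.append(bd.as_dict())
    elif mode == "relaxed":
        cache: dict[tuple, np.ndarray] = {}
        for row in _continuation_order(rows, len(offsets)):
            start = cache.get(_nearest_done(row, cache), ref)
            restraints = [TorsionRestraint(driven[d], phi0[d] + off, restraint_k)
                          for d, off in enumerate(row)]
            coords, _e, conv, mg = minimize_frame(ev, start, restraints=restraints,
                                                  gtol=1e-4)
            if not conv:
                # high-strain corner cells occasionally trap L-BFGS; retry
                # from jittered copies of the best start available
                retry_rng = np.random.default_rng(seed + 7919)
                for _retry in range(5):
                    jittered = start + retry_rng.normal(scale=0.05, size=start.shape)
                    coords, _e, conv, mg = minimize_frame(
                        ev, jittered, restraints=restraints, gtol=1e-4)
                    if conv:
                        break
            if not conv:
                raise MinimisationError(
                    f"restrained minimisation stalled at {row} (max grad {mg:.2e})")
            cache[row] = coords
        for row in rows:
            coords = cache[row]
            frames.append(coords)
            angles.append([phi0[d] + off for d, off in enumerate(row)])
            bd = ev.energy(coords)
            energies.append(bd.total)
            breakdowns.append(bd.as_dict())
    else:
        raise ValueError(f"unknown scan mode {mode!r}")

    energies = np.asarray(energies)
    noisy = energies + (rng.normal(0.0, noise_sigma, size=len(energies))
                        if noise_sigma > 0 else 0.0)
    truth = {"clean_energies": energies, "breakdowns": breakdowns,
             "noise_sigma": noise_sigma}
    return ScanTable(
        driven=driven, angles=np.asarray(angles), energies=noisy,
        frame_indices=np.arange(len(rows)), frames=frames, step=step,
        scan_range=(lo, hi), origin="absolute", truth=truth,
    )


def _continuation_order(rows, width):
    """Visit grid rows outward from the zero-offset cell so each restrained
    minimisation can start from an already-solved neighbour."""
    def sort_key(row):
        return (sum(abs(x) for x in row), row)
    return sorted(rows, key=sort_key)


def _nearest_done(row, cache):
    if not cache:
        return None
    def dist(other):
        return sum(abs(a - b) for a, b in zip(row, other))
    return min(cache, key=dist)


def generate_hessian(fixture: Fixture, displacement: float = 1e-4) -> HessianMatrix:
    """Central finite differences of the ground-truth analytic gradient."""
    ev = MMEvaluator(fixture.system, fixture.true_params)
    x0 = fixture.system.reference_geometry.ravel().copy()
    dim = len(x0)
    h = np.zeros((dim, dim))
    for m in range(dim):
        xp = x0.copy(); xp[m] += displacement
        xm = x0.copy(); xm[m] -= displacement
        _, gp = ev.energy_and_gradient(xp)
        _, gm = ev.energy_and_gradient(xm)
        h[:, m] = (gp - gm).ravel() / (2.0 * displacement)
    h = 0.5 * (h + h.T)
    return HessianMatrix(h, fixture.system.reference_geometry)
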