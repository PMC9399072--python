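import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from phasefit.core import (
    AngleParam,
    AtomSpec,
    BondParam,
    DihedralTerm,
    EnergyOptions,
    Frame,
    MMEvaluator,
    MoleculeSystem,
    ParameterSet,
    COULOMB_KCAL,
    dihedral_term_energy,
    kabsch_rmsd,
    measure_dihedral,
    mm_energy,
)
from phasefit.errors import (
    DegenerateGeometryError,
    UnderdeterminedSuperpositionError,
    UnparametrisedInstanceError,
)

TRANS = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]], dtype=float)
CIS = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]], dtype=float)


class TestMeasureDihedral:
    def test_planar_trans(self):
        assert measure_dihedral(TRANS, (0, 1, 2, 3)) == pytest.approx(180.0)

    def test_planar_cis(self):
        assert measure_dihedral(CIS, (0, 1, 2, 3)) == pytest.approx(0.0)

    def test_reversal_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = rng.normal(size=(4, 3))
            try:
                a = measure_dihedral(g, (0, 1, 2, 3))
            except DegenerateGeometryError:
                continue
            assert measure_dihedral(g, (3, 2, 1, 0)) == pytest.approx(a, abs=1e-12)

    def test_rigid_motion_invariance(self):
        # oracle: recompute via the atan2 formula after a known transform
        rng = np.random.default_rng(1)
        for i in range(10):
            g = rng.normal(size=(4, 3)) * 2
            rot = Rotation.random(random_state=i).as_matrix()
            moved = g @ rot.T + rng.normal(size=3)
            a = measure_dihedral(g, (0, 1, 2, 3))
            b = measure_dihedral(moved, (0, 1, 2, 3))
            assert b == pytest.approx(a, abs=1e-9)

    def test_collinear_raises(self):
        g = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]], dtype=float)
        with pytest.raises(DegenerateGeometryError):
            measure_dihedral(g, (0, 1, 2, 3))

    def test_range(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            g = rng.normal(size=(4, 3)) * 2
            try:
                a = measure_dihedral(g, (0, 1, 2, 3))
            except DegenerateGeometryError:
                continue
            assert -180.0 < a <= 180.0


class TestDihedralTermEnergy:
    def test_n2_delta180_at_90(self):
        assert dihedral_term_energy([DihedralTerm(1.0, 2, 180.0)], 90.0) == pytest.approx(2.0)

    def test_n2_delta180_at_0(self):
        assert dihedral_term_energy([DihedralTerm(1.0, 2, 180.0)], 0.0) == pytest.approx(0.0)

    def test_independent_scalar_oracle(self):
        terms = [DihedralTerm(0.5, 1, 0.0), DihedralTerm(1.2, 3, 180.0)]
        phi = 37.3
        expect = 0.5 * (1 + math.cos(math.radians(phi))) \
            + 1.2 * (1 + math.cos(3 * math.radians(phi) - math.pi))
        assert dihedral_term_energy(terms, phi) == pytest.approx(expect, abs=1e-12)

    @given(st.floats(-720, 720))
    @settings(max_examples=50, deadline=None)
    def test_periodicity(self, phi):
        terms = [DihedralTerm(0.7, 2, 0.0), DihedralTerm(0.3, 3, 180.0)]
        assert dihedral_term_energy(terms, phi) == pytest.approx(
            dihedral_term_energy(terms, phi + 360.0), abs=1e-9)

    @given(st.floats(-180, 180), st.integers(1, 4))
    @settings(max_examples=60, deadline=None)
    def test_delta180_identity(self, phi, n):
        # k[1 + cos(n*phi - 180)] == k[1 - cos(n*phi)]
        if n not in (1, 2, 3, 4):
            return
        k = 0.8
        lhs = dihedral_term_energy([DihedralTerm(k, n, 180.0)], phi)
        rhs = k * (1 - math.cos(n * math.radians(phi)))
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_bounds(self):
        terms = [DihedralTerm(0.5, 1, 0.0), DihedralTerm(1.2, 3, 180.0)]
        for phi in np.linspace(-180, 180, 73):
            e = dihedral_term_energy(terms, phi)
            assert -1e-12 <= e <= 2 * (0.5 + 1.2) + 1e-12

    def test_negative_k_canonicalised(self):
        t = DihedralTerm(-1.0, 2, 0.0).canonical()
        assert t.k_phi == 1.0 and t.delta == 180.0


def _ring_system():
    atoms = [AtomSpec(i, "C", f"RX{i}", 0.05 * (-1) ** i, 12.0) for i in range(6)]
    bonds = frozenset({(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0)})
    geom = np.array([
        [math.cos(2 * math.pi * i / 6) * 1.5, math.sin(2 * math.pi * i / 6) * 1.5,
         0.07 * i] for i in range(6)
    ])
    system = MoleculeSystem(atoms, bonds, geom)
    params = ParameterSet(
        bonds={system.bond_key(a, b): BondParam(280.0 + a, 1.52) for a, b in bonds},
        angles={system.angle_key(*t): AngleParam(65.0, 112.0)
                for t in system.angle_instances},
        dihedrals={system.dihedral_key(*q): [DihedralTerm(0.6, 3, 0.0),
                                             DihedralTerm(0.3, 2, 180.0)]
                   for q in system.dihedral_instances},
        nonbonded={f"RX{i}": (0.08, 1.85) for i in range(6)},
    )
    return system, params


class TestMMEnergy:
    def test_two_atom_equilibrium_zero(self, diatomic):
        system, params = diatomic
        e = mm_energy(system, params, Frame(system.reference_geometry))
        assert e.total == pytest.approx(0.0, abs=1e-12)

    def test_two_atom_displaced(self, diatomic):
        system, params = diatomic
        params.bonds[("DA1", "DA2")] = BondParam(100.0, 1.5)
        geom = np.array([[0.0, 0.0, 0.0], [1.6, 0.0, 0.0]])
        e = mm_energy(system, params, Frame(geom))
        assert e.bond == pytest.approx(1.0, abs=1e-10)

    def test_brute_force_oracle_ring(self):
        # oracle: naive instance enumeration + scalar evaluation
        system, params = _ring_system()
        rng = np.random.default_rng(5)
        coords = system.reference_geometry + rng.normal(size=(6, 3)) * 0.1
        got = mm_energy(system, params, Frame(coords))

        types = system.atom_types()
        e_bond = sum(
            params.bonds[system.bond_key(i, j)].k_b
            * (np.linalg.norm(coords[j] - coords[i])
               - params.bonds[system.bond_key(i, j)].b0) ** 2
            for i, j in sorted(system.bonds))
        from phasefit.core import measure_angle
        e_angle = 0.0
        for i, j, k in system.angle_instances:
            p = params.angles[system.angle_key(i, j, k)]
            e_angle += p.k_theta * math.radians(
                measure_angle(coords, (i, j, k)) - p.theta0) ** 2
        e_dihedral = 0.0
        for q in system.dihedral_instances:
            phi = measure_dihedral(coords, q)
            e_dihedral += dihedral_term_energy(
                params.dihedrals[system.dihedral_key(*q)], phi)
        e_nb_lj = e_nb_c = 0.0
        for i, j in system.nonbonded_pairs:
            r = np.linalg.norm(coords[j] - coords[i])
            ei, ri = params.nonbonded[types[i]]
            ej, rj = params.nonbonded[types[j]]
            eps, rmin = math.sqrt(ei * ej), ri + rj
            x = (rmin / r) ** 6
            e_nb_lj += eps * (x * x - 2 * x)
            e_nb_c += COULOMB_KCAL * system.atoms[i].charge * system.atoms[j].charge / r
        assert got.bond == pytest.approx(e_bond, abs=1e-8)
        assert got.angle == pytest.approx(e_angle, abs=1e-8)
        assert got.dihedral == pytest.approx(e_dihedral, abs=1e-8)
        assert got.lj == pytest.approx(e_nb_lj, abs=1e-8)
        assert got.coulomb == pytest.approx(e_nb_c, abs=1e-8)
        assert got.total == pytest.approx(
            e_bond + e_angle + e_dihedral + e_nb_lj + e_nb_c, abs=1e-8)

    def test_rigid_motion_invariance(self):
        system, params = _ring_system()
        ev = MMEvaluator(system, params)
        rng = np.random.default_rng(3)
        coords = system.reference_geometry + rng.normal(size=(6, 3)) * 0.05
        rot = Rotation.random(random_state=9).as_matrix()
        moved = coords @ rot.T + np.array([5.0, -3.0, 2.0])
        assert ev.energy(moved).total == pytest.approx(
            ev.energy(coords).total, abs=1e-8)

    def test_all_disabled_is_zero(self):
        system, params = _ring_system()
        opts = EnergyOptions(bonds=False, angles=False, dihedrals=False,
                             impropers=False, lj=False, coulomb=False)
        e = mm_energy(system, params, Frame(system.reference_geometry), opts)
        assert e.total == 0.0

    def test_missing_parameter_raises(self):
        system, params = _ring_system()
        del params.bonds[system.bond_key(0, 1)]
        with pytest.raises(UnparametrisedInstanceError):
            MMEvaluator(system, params)

    def test_gradient_matches_finite_difference(self):
        system, params = _ring_system()
        ev = MMEvaluator(system, params)
        rng = np.random.default_rng(7)
        coords = system.reference_geometry + rng.normal(size=(6, 3)) * 0.05
        e, grad = ev.energy_and_gradient(coords)
        h = 1e-5
        for a in range(6):
            for x in range(3):
                cp = coords.copy(); cp[a, x] += h
                cm = coords.copy(); cm[a, x] -= h
                num = (ev.energy(cp).total - ev.energy(cm).total) / (2 * h)
                assert num == pytest.approx(grad[a, x], rel=1e-4, abs=1e-6)


class TestKabschRMSD:
    def test_identical(self):
        g = np.random.default_rng(0).normal(size=(5, 3))
        assert kabsch_rmsd(g, g) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy(self):
        rng = np.random.default_rng(1)
        g = rng.normal(size=(6, 3))
        rot = Rotation.random(random_state=4).as_matrix()
        moved = g @ rot.T + np.array([1.0, 2.0, 3.0])
        assert kabsch_rmsd(g, moved) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a), abs=1e-12)

    def test_small_selection_raises(self):
        g = np.zeros((4, 3))
        with pytest.raises(UnderdeterminedSuperpositionError):
            kabsch_rmsd(g, g, selection=[0, 1])

    def test_against_rotation_search_oracle(self):
        # 4 points, one displaced by 0.4 A; oracle = optimisation over
        # Euler angles + centroid translation, independent of the SVD path
        from scipy.optimize import minimize as sp_min

        ref = np.array([[0, 0, 0], [1.5, 0, 0], [1.5, 1.5, 0], [0, 1.5, 1.0]],
                       dtype=float)
        mob = ref.copy()
        mob[3] += np.array([0.0, 0.0, 0.4])
        got = kabsch_rmsd(ref, mob)

        p = ref - ref.mean(axis=0)
        q = mob - mob.mean(axis=0)

        def rmsd_of(angles):
            rot = Rotation.from_euler("xyz", angles).as_matrix()
            return float(np.sqrt(np.mean(np.sum((p - q @ rot.T) ** 2, axis=1))))

        best = min(
            sp_min(rmsd_of, x0, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12}).fun
            for x0 in np.random.default_rng(3).uniform(-np.pi, np.pi, size=(25, 3))
        )
        assert got == pytest.approx(best, abs=1e-4)


class TestDomainTypes:
    def test_dihedral_term_invariants(self):
        with pytest.raises(ValueError):
            DihedralTerm(1.0, 5, 0.0)
        with pytest.raises(ValueError):
            DihedralTerm(1.0, 2, 90.0)

    def test_parameter_set_canonicalises_keys(self):
        ps = ParameterSet(bonds={("ZB", "AB"): BondParam(100.0, 1.5)})
        assert ("AB", "ZB") in ps.bonds

    def test_duplicate_n_rejected(self):
        with pytest.raises(ValueError):
            ParameterSet(dihedrals={("A", "B", "C", "D"): [
                DihedralTerm(1.0, 2, 0.0), DihedralTerm(0.5, 2, 180.0)]})

    def test_disconnected_graph_rejected(self):
        atoms = [AtomSpec(i, "C", "T", 0.0, 12.0) for i in range(4)]
        with pytest.raises(ValueError, match="connected"):
            MoleculeSystem(atoms, frozenset({(0, 1), (2, 3)}), np.zeros((4, 3)))

    def test_angle_and_dihedral_instances_are_simple_paths(self):
        system, _ = _ring_system()
        # 6-ring: 6 angles, 6 dihedrals, each a simple path of the graph
        assert len(system.angle_instances) == 6
        assert len(system.dihedral_instances) == 6
        for i, j, k, l in system.dihedral_instances:
            assert len({i, j, k, l}) == 4
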