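import numpy as np
import pytest

from phasefit.core import (
    AtomSpec,
    AngleParam,
    BondParam,
    MoleculeSystem,
    ParameterSet,
)
from phasefit.dihedrals import DihedralGroup
from phasefit.synthetic import FixtureSpec, generate_scan, make_fixture


@pytest.fixture(scope="session")
def chain_fixture():
    """Chain fixture with corrupted dihedrals and noiseless relaxed scans."""
    fx = make_fixture(FixtureSpec(template="chain", seed=2, perturb_params=True,
                                  perturb_scope="dihedral-only"))
    scans = [generate_scan(fx, q, scan_range=(-120, 120), step=10,
                           mode="relaxed", seed=11) for q in fx.rotatable]
    return fx, scans


@pytest.fixture(scope="session")
def fused45_fixture():
    fx = make_fixture(FixtureSpec(template="fused45", seed=11, perturb_params=True,
                                  perturb_scope="dihedral-only"))
    seen, scans = set(), []
    for q in fx.system.dihedral_instances:
        key = fx.system.dihedral_key(*q)
        if key in seen:
            continue
        seen.add(key)
        ring4 = next((r for r in fx.rings if len(r) == 4), frozenset())
        rng_, st = ((-45, 45), 5) if all(x in ring4 for x in q) else ((-90, 90), 10)
        scans.append(generate_scan(fx, q, scan_range=rng_, step=st,
                                   mode="relaxed", seed=7))
    return fx, scans


@pytest.fixture(scope="session")
def flip_fixture():
    return make_fixture(FixtureSpec(template="fused45", seed=0, flip_mode=True))


@pytest.fixture(scope="session")
def all_types_group(chain_fixture):
    fx, _scans = chain_fixture
    keys = {fx.system.dihedral_key(*q) for q in fx.system.dihedral_instances}
    return DihedralGroup("all", frozenset(keys), 0)


@pytest.fixture
def diatomic():
    """Two bonded atoms with a single harmonic bond parameter."""
    atoms = [AtomSpec(0, "C", "DA1", 0.0, 12.0), AtomSpec(1, "C", "DA2", 0.0, 12.0)]
    system = MoleculeSystem(
        atoms=atoms, bonds=frozenset({(0, 1)}),
        reference_geometry=np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]]),
    )
    params = ParameterSet(
        bonds={("DA1", "DA2"): BondParam(300.0, 1.5)},
        nonbonded={"DA1": (0.1, 1.9), "DA2": (0.1, 1.9)},
    )
    return system, params


@pytest.fixture
def water_like():
    """Bent 3-atom system: two bonds + one angle, known force constants."""
    theta = np.radians(104.0)
    geom = np.array([
        [0.96, 0.0, 0.0],
        [0.0, 0.0, 0.0],
        [0.96 * np.cos(theta), 0.96 * np.sin(theta), 0.0],
    ])
    atoms = [AtomSpec(0, "H", "WH", 0.2, 1.0), AtomSpec(1, "O", "WO", -0.4, 16.0),
             AtomSpec(2, "H", "WH", 0.2, 1.0)]
    system = MoleculeSystem(atoms=atoms, bonds=frozenset({(0, 1), (1, 2)}),
                            reference_geometry=geom)
    params = ParameterSet(
        bonds={("WH", "WO"): BondParam(450.0, 0.96)},
        angles={("WH", "WO", "WH"): AngleParam(55.0, 104.0)},
        nonbonded={"WH": (0.046, 0.22), "WO": (0.15, 1.7)},
    )
    return system, params
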