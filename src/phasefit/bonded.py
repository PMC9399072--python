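"""Harmonic bond/angle/improper fitting from a Cartesian Hessian.

Force constants come from an uncoupled per-internal projection.  The full
Wilson B matrix (first derivatives of every bond/angle/improper internal
with respect to Cartesians) is evaluated at the reference geometry, and
the distortion direction for internal q is the minimum-norm Cartesian
displacement d_q that changes q by one unit while freezing every other
internal to first order, d_q = B^+ e_q (pseudo-inverse column).  The
model distortion energy is then E(h) = 1/2 h^2 d_q^T H d_q with
Delta_q = h, so under the CHARMM convention k (x - x0)^2

    k_q = (d_q^T H d_q) / 2.

Naively displacing along B_q^T alone contaminates angle constants with
the (much stiffer) bond terms; the pseudo-inverse direction removes that
first-order coupling.  Off-diagonal internal-coordinate Hessian couplings
are still neglected, and redundant ring internals make the freeze
approximate — the documented recovery tolerances (exact for a diatomic,
a few percent for polyatomics) bound the residual error.  Equilibrium
values are taken directly from the reference geometry, which guarantees
the 0.03 A / 3 degree equilibrium envelope by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .core import (
    AngleParam,
    BondParam,
    ImproperParam,
    MoleculeSystem,
    ParameterSet,
    angle_value_and_gradient,
    bond_value_and_gradient,
    canonical_angle_key,
    canonical_bond_key,
    canonical_improper_key,
    measure_angle,
    measure_bond,
    torsion_value_and_gradient,
    wrap_angle_deg,
)
from .formats import HessianMatrix

DEFAULT_PENALTY_THRESHOLD = 10.0
TOL_BOND = 0.03    # Angstrom
TOL_ANGLE = 3.0    # degrees

Policy = Literal["penalty-threshold", "all-bonded"]


@dataclass
class PenaltySelection:
    """Which parameter keys the optimisation stage will touch."""

    selected: set[tuple]
    policy: Policy
    threshold: float
    charges_flagged: set = field(default_factory=set)


def select_parameters(params: ParameterSet, policy: Policy = "penalty-threshold",
                      threshold: float = DEFAULT_PENALTY_THRESHOLD) -> PenaltySelection:
    """Select parameters to optimise.

    penalty-threshold: a key is selected iff its penalty is *strictly*
    larger than ``threshold`` (absent annotation counts as 0).
    all-bonded: every bond/angle/dihedral/improper key is selected
    regardless of penalty.  Charge entries (penalty keys of the form
    ('charge', ...)) are flagged separately; charge fitting itself is out
    of scope here.
    """
    bonded_keys = (list(params.bonds) + list(params.angles)
                   + list(params.dihedrals) + list(params.impropers))
    if policy == "all-bonded":
        selected = set(bonded_keys)
    elif policy == "penalty-threshold":
        selected = {k for k in bonded_keys if params.penalty(k) > threshold}
    else:
        raise ValueError(f"unknown selection policy {policy!r}")
    charges = {k for k, v in params.penalties.items()
               if isinstance(k, tuple) and len(k) and k[0] == "charge" and v > threshold}
    return PenaltySelection(selected, policy, threshold, charges)


def _wilson_rows(system: MoleculeSystem):
    """(internal descriptors, stacked B matrix) for every bond, angle and
    improper instance; each descriptor is (kind, instance, value)."""
    geom = system.reference_geometry
    rows, desc = [], []
    for i, j in sorted(system.bonds):
        val, grad = bond_value_and_gradient(geom, (i, j))
        rows.append(grad.ravel())
        desc.append(("bond", (i, j), val))
    for i, j, k in system.angle_instances:
        val, grad = angle_value_and_gradient(geom, (i, j, k))
        rows.append(grad.ravel())
        desc.append(("angle", (i, j, k), val))
    for q in system.impropers:
        val, grad = torsion_value_and_gradient(geom, q)
        rows.append(grad.ravel())
        desc.append(("improper", tuple(q), val))
    return desc, np.asarray(rows)


def fit_bonds_angles(system: MoleculeSystem, hessian: HessianMatrix,
                     initial: ParameterSet, selection: PenaltySelection) -> ParameterSet:
    """Refit selected bond/angle/improper parameters from the Hessian.

    Force constants from the uncoupled pseudo-inverse projection (averaged
    over instances of a type, clipped at 0); equilibrium values measured
    on the reference geometry (averaged over instances).  Dihedral keys in
    the selection are ignored here — they are fitted from torsion scans.
    """
    geom = system.reference_geometry
    if np.abs(hessian.geometry - geom).max() > 1e-4:
        raise ValueError("Hessian geometry does not match the reference geometry")
    h = hessian.matrix
    types = system.atom_types()
    out = initial.copy()

    desc, b_mat = _wilson_rows(system)
    if not len(b_mat):
        return out
    b_pinv = np.linalg.pinv(b_mat, rcond=1e-10)

    def projected_k(row_idx: int) -> float | None:
        b_row = b_mat[row_idx]
        if np.linalg.norm(b_row) < 1e-8:
            return None
        d = b_pinv[:, row_idx]
        achieved = float(b_mat[row_idx] @ d)
        if abs(achieved) < 1e-6:
            return None
        return float(d @ h @ d) / (2.0 * achieved ** 2)

    by_key: dict[str, dict[tuple, list[tuple[float, float]]]] = {
        "bond": {}, "angle": {}, "improper": {}}
    for row_idx, (kind, inst, val) in enumerate(desc):
        if kind == "bond":
            key = canonical_bond_key(types[inst[0]], types[inst[1]])
        elif kind == "angle":
            key = canonical_angle_key(*(types[x] for x in inst))
        else:
            key = canonical_improper_key(*(types[x] for x in inst))
        if key not in selection.selected:
            continue
        k = projected_k(row_idx)
        if k is None:
            warnings.warn(f"degenerate {kind} internal {inst}; skipped", stacklevel=2)
            continue
        value = val if kind == "bond" else math.degrees(val)
        by_key[kind].setdefault(key, []).append((max(k, 0.0), value))

    for key, rows in by_key["bond"].items():
        out.bonds[key] = BondParam(float(np.mean([r[0] for r in rows])),
                                   float(np.mean([r[1] for r in rows])))
    for key, rows in by_key["angle"].items():
        out.angles[key] = AngleParam(float(np.mean([r[0] for r in rows])),
                                     float(np.mean([r[1] for r in rows])))
    for key, rows in by_key["improper"].items():
        w0 = wrap_angle_deg(float(np.mean([r[1] for r in rows])))
        out.impropers[key] = ImproperParam(float(np.mean([r[0] for r in rows])), w0)
    return out


@dataclass
class EquilibriumReport:
    records: pd.DataFrame
    passed: bool
    max_bond_deviation: float
    max_angle_deviation: float


def check_equilibria(system: MoleculeSystem, params: ParameterSet,
                     tol_bond: float = TOL_BOND,
                     tol_angle: float = TOL_ANGLE) -> EquilibriumReport:
    """Compare parameter equilibrium values with the reference geometry.

    Every bond/angle instance is measured on the reference geometry and
    compared with its parameter's b0/theta0; the overall report passes iff
    every instance lies within (tol_bond, tol_angle).
    """
    geom = system.reference_geometry
    types = system.atom_types()
    rows = []
    for i, j in sorted(system.bonds):
        key = canonical_bond_key(types[i], types[j])
        measured = measure_bond(geom, (i, j))
        dev = abs(params.bonds[key].b0 - measured)
        rows.append({"kind": "bond", "instance": f"{i}-{j}", "type": "-".join(key),
                     "equilibrium": params.bonds[key].b0, "measured": measured,
                     "deviation": dev, "tolerance": tol_bond, "pass": dev <= tol_bond})
    for i, j, k in system.angle_instances:
        key = canonical_angle_key(types[i], types[j], types[k])
        measured = measure_angle(geom, (i, j, k))
        dev = abs(params.angles[key].theta0 - measured)
        rows.append({"kind": "angle", "instance": f"{i}-{j}-{k}", "type": "-".join(key),
                     "equilibrium": params.angles[key].theta0, "measured": measured,
                     "deviation": dev, "tolerance": tol_angle, "pass": dev <= tol_angle})
    df = pd.DataFrame(rows)
    bond_devs = df.loc[df["kind"] == "bond", "deviation"]
    angle_devs = df.loc[df["kind"] == "angle", "deviation"]
    return EquilibriumReport(
        records=df,
        passed=bool(df["pass"].all()) if len(df) else True,
        max_bond_deviation=float(bond_devs.max()) if len(bond_devs) else 0.0,
        max_angle_deviation=float(angle_devs.max()) if len(angle_devs) else 0.0,
    )
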