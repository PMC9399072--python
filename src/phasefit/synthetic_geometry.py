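"""Rigid fragment rotation about a bond (torsion driving).

Shared by the synthetic scan generator (rigid mode) and the conformer
search (random torsion perturbations).  The bond must not be part of a
ring — ring closure cannot be preserved by a rigid rotation; drive ring
torsions with a restrained relaxation instead.
"""

from __future__ import annotations

import math

import numpy as np

from .core import MoleculeSystem, measure_dihedral, wrap_angle_deg
from .errors import RingTorsionError


def downstream_atoms(system: MoleculeSystem, j: int, k: int) -> set[int]:
    """Atoms on the k side after removing bond (j, k); error if in a ring."""
    adj = system.adjacency
    seen = {k}
    stack = [k]
    while stack:
        cur = stack.pop()
        for nb in adj[cur]:
            if cur == k and nb == j:
                continue
            if nb == j:
                raise RingTorsionError(
                    f"bond ({j},{k}) lies in a ring; rigid rotation cannot "
                    "preserve ring closure — use a relaxed (restrained) scan")
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen


def rotate_fragment(system: MoleculeSystem, coords: np.ndarray,
                    quadruple, angle_deg: float, relative: bool = True) -> np.ndarray:
    """Rotate the downstream fragment of a torsion to change its angle.

    ``relative=True`` changes the torsion by ``angle_deg``; otherwise the
    torsion is set to the absolute value ``angle_deg``.  Exact (no
    minimisation); raises RingTorsionError for ring-internal bonds.
    """
    coords = np.asarray(coords, dtype=float).copy()
    i, j, k, l = quadruple
    moving = sorted(downstream_atoms(system, j, k) - {k})
    current = measure_dihedral(coords, quadruple)
    target = wrap_angle_deg(current + angle_deg) if relative else wrap_angle_deg(angle_deg)
    delta = math.radians(wrap_angle_deg(target - current))
    for sign in (1.0, -1.0):
        trial = _apply_rotation(coords, moving, coords[j], coords[k], sign * delta)
        if abs(wrap_angle_deg(measure_dihedral(trial, quadruple) - target)) < 1e-6:
            return trial
    raise RuntimeError("fragment rotation failed to reach the target torsion")


def _apply_rotation(coords, moving, pj, pk, angle_rad):
    axis = pk - pj
    axis = axis / np.linalg.norm(axis)
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    ux, uy, uz = axis
    rot = np.array([
        [c + ux * ux * (1 - c), ux * uy * (1 - c) - uz * s, ux * uz * (1 - c) + uy * s],
        [uy * ux * (1 - c) + uz * s, c + uy * uy * (1 - c), uy * uz * (1 - c) - ux * s],
        [uz * ux * (1 - c) - uy * s, uz * uy * (1 - c) + ux * s, c + uz * uz * (1 - c)],
    ])
    out = coords.copy()
    out[moving] = (coords[moving] - pk) @ rot.T + pk
    return out
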