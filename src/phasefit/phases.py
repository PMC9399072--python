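"""Geometry-based prediction of dihedral phase shifts.

For an additive cosine series fitted with k >= 0, the phase shift of each
term should place that term's local minimum at the equilibrium torsion:
evaluate cos(n*phi0 - delta) for delta in {0, 180} and keep the smaller.
When the two candidates are nearly equal the decision is flagged
ambiguous and both are reported, so alternative assignments can be
enumerated and validated downstream.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .core import (
    ALLOWED_MULTIPLICITIES,
    MoleculeSystem,
    ParameterSet,
    canonical_dihedral_key,
    measure_dihedral,
)
from .errors import ConfigurationError, UnknownTargetError

DEFAULT_TIE_TOL = 0.05  # on the summed-cosine scale


@dataclass(frozen=True)
class PhaseDecision:
    """One (type, n) phase choice with its score gap and provenance."""

    type_key: tuple[str, ...]
    n: int
    delta: float
    score_gap: float
    ambiguous: bool
    source: str = "geometry"  # geometry | double-bond-rule | manual-override
    candidates: tuple[float, ...] = (0.0, 180.0)

    def __post_init__(self):
        if float(self.delta) not in (0.0, 180.0):
            raise ValueError("delta must be 0 or 180")
        if self.score_gap < 0:
            raise ValueError("score_gap must be >= 0")


def predict_phase(n: int, phi0: float, tie_tol: float = DEFAULT_TIE_TOL,
                  type_key: tuple[str, ...] = ("?", "?", "?", "?")) -> PhaseDecision:
    """Choose delta in {0, 180} minimising cos(n*phi0 - delta).

    ``score_gap`` is |cos(n*phi0) - cos(n*phi0 - 180)| = 2|cos(n*phi0)|;
    the decision is ambiguous iff the gap is below ``tie_tol``, in which
    case both candidates are reported (geometry-derived delta first).
    """
    if n not in ALLOWED_MULTIPLICITIES:
        raise ValueError(f"multiplicity must be in {{1,2,3,4,6}}, got {n}")
    return _decide(type_key, n, [phi0], tie_tol)


def _decide(type_key, n, phi0s: Sequence[float], tie_tol: float) -> PhaseDecision:
    s0 = sum(math.cos(math.radians(n * p)) for p in phi0s)
    s180 = sum(math.cos(math.radians(n * p) - math.pi) for p in phi0s)
    delta = 0.0 if s0 < s180 else 180.0
    gap = abs(s0 - s180)
    ambiguous = gap < tie_tol
    candidates = (delta, 180.0 - delta) if ambiguous else (delta,)
    return PhaseDecision(canonical_dihedral_key(*type_key), n, delta, gap,
                         ambiguous, "geometry", candidates)


def predict_phases(system: MoleculeSystem, params: ParameterSet,
                   tie_tol: float = DEFAULT_TIE_TOL) -> list[PhaseDecision]:
    """Phase decisions for every (dihedral type, n) pair in ``params``.

    A type with several geometric instances is decided by the *summed*
    criterion: delta minimises sum_i cos(n*phi0_i - delta), because the sum
    is what enters the additive energy.  Types with no instance in the
    system produce an orphan-parameter warning, not an error.
    """
    geometry = system.reference_geometry
    decisions: list[PhaseDecision] = []
    for key in sorted(params.dihedrals):
        instances = system.instances_of_dihedral_type(key)
        if not instances:
            warnings.warn(f"dihedral parameter {key} has no instance in the system",
                          stacklevel=2)
            continue
        phi0s = [measure_dihedral(geometry, q) for q in instances]
        for term in params.dihedrals[key]:
            decisions.append(_decide(key, term.n, phi0s, tie_tol))
    return decisions


def apply_double_bond_rule(decisions: Iterable[PhaseDecision],
                           system: MoleculeSystem) -> list[PhaseDecision]:
    """Force delta=180 for every n=2 term whose central bond has order 2.

    Idempotent; decisions for other multiplicities or single bonds pass
    through unchanged.  Requires ``system.bond_orders``.
    """
    if system.bond_orders is None:
        raise ConfigurationError(
            "double-bond rule requested but the system carries no bond orders")
    double_bond_types: set[tuple[str, ...]] = set()
    types = system.atom_types()
    for (i, j, k, l) in system.dihedral_instances:
        order = system.bond_orders.get((min(j, k), max(j, k)), 1)
        if order == 2:
            double_bond_types.add(canonical_dihedral_key(*(types[x] for x in (i, j, k, l))))
    out = []
    for d in decisions:
        if d.n == 2 and d.type_key in double_bond_types:
            out.append(replace(d, delta=180.0, ambiguous=False,
                               source="double-bond-rule", candidates=(180.0,)))
        else:
            out.append(d)
    return out


PhaseAssignment = dict  # (type_key, n) -> delta


def assignment_from_decisions(decisions: Iterable[PhaseDecision]) -> PhaseAssignment:
    return {(d.type_key, d.n): d.delta for d in decisions}


def enumerate_alternatives(decisions: Sequence[PhaseDecision],
                           overrides: Iterable[tuple[tuple[str, ...], int]] | None = None,
                           cap: int = 16) -> list[PhaseAssignment]:
    """Enumerate complete phase assignments: default first, then flips.

    The flippable set is the union of ambiguous decisions and manually
    named (type, n) overrides; subsets are enumerated in increasing size
    and the list is truncated at ``cap`` assignments.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    decisions = list(decisions)
    known = {(d.type_key, d.n) for d in decisions}
    flippable: list[tuple[tuple[str, ...], int]] = [
        (d.type_key, d.n) for d in decisions if d.ambiguous
    ]
    for target in overrides or ():
        key = (canonical_dihedral_key(*target[0]), target[1])
        if key not in known:
            raise UnknownTargetError(f"override names unknown dihedral term {key}")
        if key not in flippable:
            flippable.append(key)

    base = assignment_from_decisions(decisions)
    assignments = [dict(base)]
    for size in range(1, len(flippable) + 1):
        for subset in itertools.combinations(flippable, size):
            a = dict(base)
            for key in subset:
                a[key] = 180.0 - a[key]
            assignments.append(a)
            if len(assignments) >= cap:
                return assignments
    return assignments


def format_decisions(decisions: Sequence[PhaseDecision]) -> str:
    """Delimited-text phase report (one line per decision)."""
    lines = ["type\tn\tdelta\tscore_gap\tambiguous\tsource"]
    for d in decisions:
        lines.append(
            f"{'-'.join(d.type_key)}\t{d.n}\t{d.delta:.0f}\t{d.score_gap:.6f}"
            f"\t{int(d.ambiguous)}\t{d.source}"
        )
    return "\n".join(lines) + "\n"
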