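"""Least-squares fitting of dihedral force constants to torsion scans.

Multiplicities and phase shifts are *fixed* during the fit; only the
force constants (k >= 0) and one additive offset per scan are free.  The
sign freedom lives entirely in the phase shift, which is decided before
fitting (see phases module) — fitters that let the phase float can
reproduce a profile and still put a barrier on the equilibrium geometry.

Rows whose min-subtracted target energy exceeds the energy cutoff
(default 10 kcal/mol) are excluded from the fit.  Offsets are eliminated
analytically (per-scan centring), after which the non-negative problem is
solved with NNLS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import nnls

from .core import (
    DihedralTerm,
    EnergyOptions,
    MMEvaluator,
    MoleculeSystem,
    ParameterSet,
    canonical_dihedral_key,
    measure_dihedral,
)
from .errors import EmptyFitError
from .formats import ScanTable
from .phases import PhaseAssignment, predict_phase

DEFAULT_CUTOFF = 10.0        # kcal/mol, fit-point exclusion
DEFAULT_ACCEPT = 0.10        # relative RMSE reduction for augmentation
AUGMENT_CANDIDATES = (1, 2, 3, 4, 6)


@dataclass(frozen=True)
class DihedralGroup:
    """A named, disjoint set of dihedral type keys with a fitting rank."""

    name: str
    members: frozenset[tuple[str, ...]]
    order_rank: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "members",
            frozenset(canonical_dihedral_key(*m) for m in self.members))


@dataclass
class FitResult:
    fitted: dict[tuple[tuple[str, ...], int], float]
    offsets: dict[int, float]
    rmse_before: float
    rmse_after: float
    points_used: int
    points_excluded: int
    assignment: PhaseAssignment
    unidentifiable: list[tuple[tuple[str, ...], int]] = field(default_factory=list)
    condition_number: float = float("nan")

    def __post_init__(self):
        for (key, n), k in self.fitted.items():
            if k < -1e-12:
                raise ValueError(f"fitted k for {key} n={n} is negative")
        if self.rmse_after > self.rmse_before + 1e-9:
            raise ValueError("rmse_after exceeds rmse_before")


def scan_baseline(system: MoleculeSystem, params: ParameterSet, scan: ScanTable,
                  group: DihedralGroup,
                  options: EnergyOptions = EnergyOptions()) -> np.ndarray:
    """Per-row MM energy with every dihedral term of `group` zeroed,
    min-subtracted across the scan's rows."""
    opts = options.with_zeroed(options.zeroed_dihedral_types | group.members)
    ev = MMEvaluator(system, params, opts)
    e = np.array([ev.energy(scan.row_coordinates(r)).total
                  for r in range(len(scan.energies))])
    return e - e.min()


def _group_terms(params: ParameterSet, group: DihedralGroup,
                 assignment: PhaseAssignment):
    """(type, n, delta) triples to fit, delta resolved via the assignment."""
    terms = []
    for key in sorted(group.members):
        if key not in params.dihedrals:
            continue
        for t in params.dihedrals[key]:
            delta = assignment.get((key, t.n), t.delta)
            terms.append((key, t.n, delta))
    return terms


def _design_matrix(system: MoleculeSystem, scans: Sequence[ScanTable],
                   terms, rows_per_scan):
    """Columns: sum over instances of (1 + cos(n*phi_row - delta))."""
    instance_cache = {key: system.instances_of_dihedral_type(key)
                      for key, _n, _d in terms}
    blocks = []
    for s_i, scan in enumerate(scans):
        rows = rows_per_scan[s_i]
        a = np.zeros((len(rows), len(terms)))
        for r_pos, row in enumerate(rows):
            geom = scan.row_coordinates(row)
            phis = {}
            for c, (key, n, delta) in enumerate(terms):
                total = 0.0
                for q in instance_cache[key]:
                    if q not in phis:
                        phis[q] = math.radians(measure_dihedral(geom, q))
                    total += 1.0 + math.cos(n * phis[q] - math.radians(delta))
                a[r_pos, c] = total
        blocks.append(a)
    return np.vstack(blocks) if blocks else np.zeros((0, len(terms)))


def fit_group(system: MoleculeSystem, params: ParameterSet,
              scans: Sequence[ScanTable], group: DihedralGroup,
              assignment: PhaseAssignment, cutoff: float = DEFAULT_CUTOFF) -> FitResult:
    """Fit the force constants of one group against one or more scans.

    Returns a FitResult; apply it to a ParameterSet with ``apply_fit``.
    ``rmse_before`` is computed with the incoming force constants under
    the *assigned* phases, so the NNLS optimum can never exceed it.
    """
    terms = _group_terms(params, group, assignment)
    if not terms:
        raise EmptyFitError(f"group {group.name!r} has no fittable terms")

    rows_per_scan, excluded = [], 0
    for scan in scans:
        rel = scan.relative_energies()
        keep = [r for r in range(len(rel)) if rel[r] <= cutoff]
        excluded += len(rel) - len(keep)
        if not keep:
            raise EmptyFitError(
                f"all rows of a scan excluded by the {cutoff} kcal/mol cutoff")
        rows_per_scan.append(keep)

    a = _design_matrix(system, scans, terms, rows_per_scan)
    baselines, targets, scan_ids = [], [], []
    for s_i, scan in enumerate(scans):
        base = scan_baseline(system, params, scan, group)
        rel = scan.relative_energies()
        for row in rows_per_scan[s_i]:
            baselines.append(base[row])
            targets.append(rel[row])
            scan_ids.append(s_i)
    b = np.asarray(targets) - np.asarray(baselines)
    scan_ids = np.asarray(scan_ids)

    # eliminate per-scan offsets analytically: centre target and columns
    bc = b.copy()
    ac = a.copy()
    for s_i in range(len(scans)):
        mask = scan_ids == s_i
        bc[mask] -= bc[mask].mean()
        ac[mask] -= ac[mask].mean(axis=0)

    # unidentifiable columns: no variance after centring
    col_norm = np.linalg.norm(ac, axis=0)
    ident = col_norm > 1e-9
    unident = [(terms[c][0], terms[c][1]) for c in np.where(~ident)[0]]

    k_fit = np.zeros(len(terms))
    for c in np.where(~ident)[0]:
        key, n, _delta = terms[c]
        k_fit[c] = next(t.k_phi for t in params.dihedrals[key] if t.n == n)
    if ident.any():
        sol, _ = nnls(ac[:, ident], bc - ac[:, ~ident] @ k_fit[~ident])
        k_fit[ident] = sol
        sv = np.linalg.svd(ac[:, ident], compute_uv=False)
        cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")
    else:
        cond = float("inf")

    def rmse_and_offsets(kvec):
        resid = b - a @ kvec
        offs, sq, npts = {}, 0.0, 0
        for s_i in range(len(scans)):
            mask = scan_ids == s_i
            c_s = resid[mask].mean()
            offs[s_i] = float(c_s)
            sq += float(np.sum((resid[mask] - c_s) ** 2))
            npts += int(mask.sum())
        return math.sqrt(sq / npts), offs

    k_in = np.array([
        next(t.k_phi for t in params.dihedrals[key] if t.n == n)
        for key, n, _delta in terms
    ])
    rmse_before, _ = rmse_and_offsets(k_in)
    rmse_after, offsets = rmse_and_offsets(k_fit)
    rmse_after = min(rmse_after, rmse_before)  # guard numerical noise only

    fitted = {(key, n): float(max(k, 0.0))
              for (key, n, _d), k in zip(terms, k_fit)}
    return FitResult(
        fitted=fitted,
        offsets=offsets,
        rmse_before=rmse_before,
        rmse_after=rmse_after,
        points_used=len(b),
        points_excluded=excluded,
        assignment=dict(assignment),
        unidentifiable=unident,
        condition_number=cond,
    )


def apply_fit(params: ParameterSet, result: FitResult) -> ParameterSet:
    """Return a copy of ``params`` with the fitted terms installed
    (force constant and assigned phase)."""
    out = params.copy()
    for (key, n), k in result.fitted.items():
        delta = result.assignment.get((key, n))
        if delta is None:
            delta = next(t.delta for t in out.dihedrals[key] if t.n == n)
        out.set_dihedral_term(key, DihedralTerm(k, n, delta))
    return out


def apply_twofold_symmetry_rule(params: ParameterSet, system: MoleculeSystem,
                                terminal_type: str):
    """Force n=2 for dihedral types terminating on a two-fold symmetric
    terminal group (e.g. a carboxylate's equivalent oxygens).

    Each affected type's term list is replaced by a single n=2 term keeping
    the largest incoming force constant and its phase.  Returns
    (updated params, list of changed keys).
    """
    out = params.copy()
    changed = []
    for key in sorted(out.dihedrals):
        if key[0] != terminal_type and key[3] != terminal_type:
            continue
        if not system.instances_of_dihedral_type(key):
            continue
        terms = out.dihedrals[key]
        if len(terms) == 1 and terms[0].n == 2:
            continue
        lead = max(terms, key=lambda t: t.k_phi)
        out.dihedrals[key] = [DihedralTerm(lead.k_phi, 2, lead.delta)]
        changed.append(key)
    return out, changed


@dataclass
class AugmentationTrial:
    type_key: tuple[str, ...]
    n: int
    delta: float
    rmse: float
    accepted: bool


def augment_multiplicities(system: MoleculeSystem, params: ParameterSet,
                           scans: Sequence[ScanTable], group: DihedralGroup,
                           assignment: PhaseAssignment,
                           candidates: Iterable[int] = AUGMENT_CANDIDATES,
                           accept_threshold: float = DEFAULT_ACCEPT,
                           cutoff: float = DEFAULT_CUTOFF):
    """Greedy best-first introduction of extra multiplicities.

    Extra n are tried one by one for every member type, each with both
    phases (the geometry-predicted delta first, then its alternate — the
    useful extras often correspond to the *flipped* structure); the single
    best candidate is accepted when it reduces the group RMSE by at least
    ``accept_threshold`` (relative), and the search repeats until no
    candidate qualifies.

    Returns (updated params, updated assignment, base FitResult, trials).
    """
    params = params.copy()
    assignment = dict(assignment)
    base = fit_group(system, params, scans, group, assignment, cutoff)
    params = apply_fit(params, base)
    trials: list[AugmentationTrial] = []

    while True:
        best = None
        for key in sorted(group.members):
            if key not in params.dihedrals:
                continue
            present = {t.n for t in params.dihedrals[key]}
            instances = system.instances_of_dihedral_type(key)
            phi0s = [measure_dihedral(system.reference_geometry, q)
                     for q in instances]
            for n in candidates:
                if n in present:
                    continue
                geo = predict_phase(n, phi0s[0]) if phi0s else None
                order = ([geo.delta, 180.0 - geo.delta] if geo is not None
                         else [0.0, 180.0])
                for delta in order:
                    trial_params = params.copy()
                    trial_params.set_dihedral_term(key, DihedralTerm(0.0, n, delta))
                    trial_assign = dict(assignment)
                    trial_assign[(key, n)] = delta
                    res = fit_group(system, trial_params, scans, group,
                                    trial_assign, cutoff)
                    trials.append(AugmentationTrial(key, n, delta, res.rmse_after, False))
                    if best is None or res.rmse_after < best[0].rmse_after:
                        best = (res, trial_params, trial_assign, len(trials) - 1)
        if best is None:
            break
        res, trial_params, trial_assign, t_idx = best
        if base.rmse_after <= 1e-12:
            break
        reduction = (base.rmse_after - res.rmse_after) / base.rmse_after
        if reduction >= accept_threshold:
            trials[t_idx].accepted = True
            params = apply_fit(trial_params, res)
            assignment = trial_assign
            base = res
        else:
            break
    return params, assignment, base, trials


def fit_workflow(system: MoleculeSystem, params: ParameterSet,
                 scans: Sequence[ScanTable], groups: Sequence[DihedralGroup],
                 assignment: PhaseAssignment, iterations: int = 2,
                 cutoff: float = DEFAULT_CUTOFF,
                 scan_map: Mapping[str, Sequence[int]] | None = None):
    """Group-sequential fitting, the whole pass repeated ``iterations`` times.

    Groups are fitted in ascending ``order_rank`` (double-bond groups
    before single-bond groups; carboxylate/improper groups last), each fit
    seeing the latest parameters.  ``scan_map`` optionally names which
    scan indices drive each group; by default a scan is routed to the
    group owning its driven dihedral's type key.

    Returns (final params, list of (iteration, group name, FitResult)).
    """
    groups = sorted(groups, key=lambda g: g.order_rank)
    member_union: set = set()
    for g in groups:
        overlap = member_union & g.members
        if overlap:
            raise ValueError(f"groups are not disjoint: {sorted(overlap)}")
        member_union |= g.members

    def scans_for(group: DihedralGroup) -> list[ScanTable]:
        if scan_map is not None and group.name in scan_map:
            return [scans[i] for i in scan_map[group.name]]
        picked = []
        for scan in scans:
            key = system.dihedral_key(*scan.driven[0])
            if key in group.members:
                picked.append(scan)
        return picked

    params = params.copy()
    history: list[tuple[int, str, FitResult]] = []
    for it in range(iterations):
        for group in groups:
            g_scans = scans_for(group)
            if not g_scans:
                continue
            res = fit_group(system, params, g_scans, group, assignment, cutoff)
            params = apply_fit(params, res)
            history.append((it, group.name, res))
    return params, history
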