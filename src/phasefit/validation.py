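"""Desk-scale validation of fitted parameters.

Instead of solvated MD (out of scope here), validation compares MM vs
target torsion profiles, locates profile minima, runs a seeded
multi-start conformer search on the full MM model with local
minimisation, clusters the minimised frames with the GROMOS
neighbour-count method at an RMSD cutoff, and reports cluster RMSDs to
the reference geometry on a heavy-atom selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (
    Frame,
    MMEvaluator,
    MoleculeSystem,
    ParameterSet,
    kabsch_rmsd,
    measure_dihedral,
    minimize_frame,
    wrap_angle_deg,
)
from .errors import MinimisationError, TooSmallGridError
from .formats import ScanTable
from .synthetic_geometry import rotate_fragment  # shared torsion driver

DEFAULT_CLUSTER_CUTOFF = 0.2    # Angstrom, GROMOS RMSD cutoff
DEFAULT_VERDICT_RMSD = 0.15     # Angstrom, top-cluster pass threshold
DEFAULT_MINIMUM_TOL = 15.0      # degrees, MM-minimum vs reference torsion


def mm_profile(system: MoleculeSystem, params: ParameterSet,
               scan: ScanTable) -> np.ndarray:
    """Min-subtracted MM energies on the scan's stored geometries."""
    ev = MMEvaluator(system, params)
    e = np.array([ev.energy(scan.row_coordinates(r)).total
                  for r in range(len(scan.energies))])
    return e - e.min()


def profile_rmse(system: MoleculeSystem, params: ParameterSet,
                 scan: ScanTable) -> float:
    """RMSE between the MM profile and the scan's (relative) target
    energies, after removing the free additive offset between the two."""
    mm = mm_profile(system, params, scan)
    ref = scan.relative_energies()
    resid = ref - mm
    resid = resid - resid.mean()
    return float(np.sqrt(np.mean(resid ** 2)))


@dataclass
class GridMinimum:
    position: tuple[float, ...]
    value: float
    index: tuple[int, ...]


@dataclass
class MinimaReport:
    minima: list[GridMinimum]
    flip_barrier: float | None = None  # between the two lowest minima (2D)


def locate_minima(angles, energies, periodic: bool | None = None) -> MinimaReport:
    """Grid minima of a 1D or 2D profile, sorted by energy.

    1D: interior points lower than both neighbours; periodic wrap applies
    only when the grid spans 360 degrees.  2D: points lower than all 8
    neighbours.  For 2D the report also carries the flip barrier: the
    lowest achievable maximum energy over monotone staircase paths
    between the two lowest minima, minus the lower minimum.
    """
    energies = np.asarray(energies, dtype=float)
    if energies.ndim == 1:
        return _locate_minima_1d(np.asarray(angles, dtype=float), energies, periodic)
    if energies.ndim == 2:
        return _locate_minima_2d(angles, energies)
    raise ValueError("profile must be 1D or 2D")


def _locate_minima_1d(angles, energies, periodic):
    n = len(energies)
    if n < 3:
        raise TooSmallGridError("need at least 3 grid points per dimension")
    span = angles[-1] - angles[0]
    step = abs(angles[1] - angles[0])
    if periodic is None:
        periodic = abs(span - 360.0) < 1e-6 or abs(span - (360.0 - step)) < 1e-6
    if periodic and abs(span - 360.0) < 1e-6:
        # the two ends are the same periodic point; drop the duplicate
        angles = angles[:-1]
        energies = energies[:-1]
        n -= 1
    minima = []
    rng = range(n) if periodic else range(1, n - 1)
    for i in rng:
        left = energies[(i - 1) % n]
        right = energies[(i + 1) % n]
        if energies[i] < left and energies[i] < right:
            minima.append(GridMinimum((float(angles[i]),), float(energies[i]), (i,)))
    minima.sort(key=lambda m: m.value)
    return MinimaReport(minima)


def _locate_minima_2d(angles, energies):
    a1, a2 = (np.asarray(a, dtype=float) for a in angles)
    n1, n2 = energies.shape
    if n1 < 3 or n2 < 3:
        raise TooSmallGridError("need at least 3 grid points per dimension")
    minima = []
    for i in range(1, n1 - 1):
        for j in range(1, n2 - 1):
            window = energies[i - 1:i + 2, j - 1:j + 2]
            if energies[i, j] < window.min(initial=np.inf, where=~_centre_mask()):
                minima.append(GridMinimum((float(a1[i]), float(a2[j])),
                                          float(energies[i, j]), (i, j)))
    minima.sort(key=lambda m: m.value)
    barrier = None
    if len(minima) >= 2:
        barrier = _staircase_barrier(energies, minima[0].index, minima[1].index)
        barrier -= minima[0].value
    return MinimaReport(minima, barrier)


def _centre_mask():
    m = np.zeros((3, 3), dtype=bool)
    m[1, 1] = True
    return m


def _staircase_barrier(energies, start, end) -> float:
    """Minimum over monotone staircase paths of the path's maximum energy."""
    (i0, j0), (i1, j1) = start, end
    si = 1 if i1 >= i0 else -1
    sj = 1 if j1 >= j0 else -1
    ni = abs(i1 - i0) + 1
    nj = abs(j1 - j0) + 1
    best = np.full((ni, nj), np.inf)
    best[0, 0] = energies[i0, j0]
    for a in range(ni):
        for b in range(nj):
            if a == 0 and b == 0:
                continue
            e = energies[i0 + si * a, j0 + sj * b]
            cands = []
            if a > 0:
                cands.append(best[a - 1, b])
            if b > 0:
                cands.append(best[a, b - 1])
            best[a, b] = max(min(cands), e)
    return float(best[-1, -1])


# ---------------------------------------------------------------------------
# conformer search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TorsionPerturbation:
    """Spec for random starting-structure generation: rotatable (non-ring)
    dihedrals and the perturbation amplitude in degrees."""

    dihedrals: tuple[tuple[int, int, int, int], ...]
    amplitude_deg: float = 120.0
    cartesian_jitter: float = 0.0   # optional extra, Angstrom
    # fraction of starts taken from the z-mirrored reference: reflection is
    # energy-preserving, so this probes whether the mirror-image (e.g. ring
    # pucker flipped) conformer is a distinct minimum — ring-internal
    # torsions cannot be driven rigidly
    mirror_fraction: float = 0.0


def conformer_search(system: MoleculeSystem, params: ParameterSet,
                     perturb: TorsionPerturbation, n_starts: int,
                     seed: int, gtol: float = 1e-6) -> list[Frame]:
    """Multi-start local minimisation from torsion-perturbed geometries.

    Deterministic given ``seed``.  Starts whose minimisation fails to
    converge are dropped (reported via the returned frames' count).
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    ev = MMEvaluator(system, params)
    ref = system.reference_geometry
    frames: list[Frame] = []
    for _ in range(n_starts):
        coords = ref.copy()
        if perturb.mirror_fraction > 0 and rng.random() < perturb.mirror_fraction:
            centre = coords.mean(axis=0)
            coords = coords - centre
            coords[:, 2] *= -1.0
            coords = coords + centre
        for quad in perturb.dihedrals:
            delta = float(rng.uniform(-perturb.amplitude_deg, perturb.amplitude_deg))
            coords = rotate_fragment(system, coords, quad, delta, relative=True)
        if perturb.cartesian_jitter > 0:
            coords = coords + rng.normal(scale=perturb.cartesian_jitter,
                                         size=coords.shape)
        final, energy, converged, _mg = minimize_frame(ev, coords, gtol=gtol)
        if not converged:
            continue
        frames.append(Frame(final, energy=energy))
    if not frames:
        raise MinimisationError("no conformer-search start converged")
    return frames


# ---------------------------------------------------------------------------
# GROMOS clustering
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    members: list[int]
    centroid: int
    fraction: float
    rmsd_to_reference: float | None = None


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    cutoff: float

    def fractions(self) -> list[float]:
        return [c.fraction for c in self.clusters]


def gromos_cluster(frames: Sequence[Frame | np.ndarray],
                   selection: Iterable[int] | None = None,
                   cutoff: float = DEFAULT_CLUSTER_CUTOFF,
                   reference: np.ndarray | None = None) -> ClusterSet:
    """GROMOS neighbour-count clustering at an RMSD cutoff.

    Iteratively: the frame with the most neighbours within ``cutoff``
    (pairwise Kabsch RMSD on ``selection``) seeds a cluster with those
    neighbours and is removed; ties break on the lowest frame index.
    Clusters come back ordered by descending size.
    """
    coords = [f.coordinates if isinstance(f, Frame) else np.asarray(f, dtype=float)
              for f in frames]
    n = len(coords)
    sel = sorted(selection) if selection is not None else None
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = kabsch_rmsd(coords[i], coords[j], sel)
            dist[i, j] = dist[j, i] = d
    remaining = list(range(n))
    clusters: list[Cluster] = []
    while remaining:
        best_idx, best_neighbours = None, None
        for i in remaining:
            nb = [j for j in remaining if dist[i, j] <= cutoff]
            if best_neighbours is None or len(nb) > len(best_neighbours):
                best_idx, best_neighbours = i, nb
        members = sorted(best_neighbours)
        rmsd_ref = None
        if reference is not None:
            rmsd_ref = kabsch_rmsd(reference, coords[best_idx], sel)
        clusters.append(Cluster(members, best_idx, len(members) / n, rmsd_ref))
        remaining = [i for i in remaining if i not in set(members)]
    clusters.sort(key=lambda c: (-len(c.members), c.centroid))
    return ClusterSet(clusters, cutoff)


# ---------------------------------------------------------------------------
# full validation report
# ---------------------------------------------------------------------------

@dataclass
class ValidationConfig:
    cluster_cutoff: float = DEFAULT_CLUSTER_CUTOFF
    verdict_rmsd: float = DEFAULT_VERDICT_RMSD
    minimum_tol_deg: float = DEFAULT_MINIMUM_TOL
    n_starts: int = 30
    seed: int = 0
    selection_name: str = "ring-heavy"
    flip_fraction: float = 0.2   # a second cluster above this marks a flip


@dataclass
class ScanCheck:
    rmse: float
    mm_minimum_deg: float
    reference_deg: float
    minimum_ok: bool


@dataclass
class ValidationReport:
    scan_checks: list[ScanCheck]
    cluster_set: ClusterSet | None
    top_cluster_rmsd: float | None
    flip_detected: bool
    verdict: str  # "pass" | "fail"
    frames: list[Frame] | None = None  # conformer-search output

    @property
    def passed(self) -> bool:
        return self.verdict == "pass"


def validate_parameters(system: MoleculeSystem, params: ParameterSet,
                        scans: Sequence[ScanTable],
                        perturb: TorsionPerturbation | None = None,
                        config: ValidationConfig = ValidationConfig()) -> ValidationReport:
    """Scan-profile RMSE + minima check + conformer-search clustering.

    The verdict is "pass" iff every 1D scan's MM global grid minimum lies
    within ``minimum_tol_deg`` of the reference torsion and (when a
    conformer search ran) the top cluster's RMSD to the reference
    geometry on the configured selection is <= ``verdict_rmsd``.
    """
    checks: list[ScanCheck] = []
    for scan in scans:
        if scan.ndim != 1:
            continue
        mm = mm_profile(system, params, scan)
        rmse = profile_rmse(system, params, scan)
        i_min = int(np.argmin(mm))
        mm_min_angle = float(scan.angles[i_min, 0])
        ref_angle = measure_dihedral(system.reference_geometry, scan.driven[0])
        diff = abs(wrap_angle_deg(mm_min_angle - ref_angle))
        checks.append(ScanCheck(rmse, wrap_angle_deg(mm_min_angle), ref_angle,
                                diff <= config.minimum_tol_deg))

    cluster_set = None
    top_rmsd = None
    flip = False
    frames = None
    if perturb is not None:
        frames = conformer_search(system, params, perturb, config.n_starts,
                                  config.seed)
        sel = system.selections.get(config.selection_name)
        if sel is None:
            sel = frozenset(i for i, a in enumerate(system.atoms)
                            if a.element.upper() != "H")
        cluster_set = gromos_cluster(frames, sel, config.cluster_cutoff,
                                     reference=system.reference_geometry)
        frames = list(frames)
        top_rmsd = cluster_set.clusters[0].rmsd_to_reference
        flip = (len(cluster_set.clusters) >= 2
                and cluster_set.clusters[1].fraction >= config.flip_fraction)

    ok = all(c.minimum_ok for c in checks)
    if top_rmsd is not None:
        # with a near-degenerate flip either dominant conformer may win the
        # top cluster; accept when any dominant cluster matches the reference
        dominant = [c for c in (cluster_set.clusters if cluster_set else [])
                    if c.fraction >= config.flip_fraction]
        rmsds = [c.rmsd_to_reference for c in dominant] or [top_rmsd]
        ok = ok and min(rmsds) <= config.verdict_rmsd
    return ValidationReport(checks, cluster_set, top_rmsd, flip,
                            "pass" if ok else "fail", frames)


def rank_assignments(reports: Mapping[str, ValidationReport]) -> list[str]:
    """Order phase assignments: top-cluster RMSD first, then scan RMSE."""
    def score(name):
        r = reports[name]
        rmsd = r.top_cluster_rmsd if r.top_cluster_rmsd is not None else math.inf
        rmse = float(np.mean([c.rmse for c in r.scan_checks])) if r.scan_checks else math.inf
        return (rmsd, rmse)
    return sorted(reports, key=score)
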