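"""Ensemble post-processing: RMSD, hierarchical clustering with top1/top5
reporting, funneling profiles across the replica ladder, lowest-restraint-
energy structure identification, and violation reports on accuracy grids.

The prediction protocol mirrors standard practice for restrained-ensemble
methods: cluster the second half of the lowest-temperature replicas by
pairwise Cα RMSD (average linkage, fixed distance cutoff), take the
centroid (medoid) of the most populated cluster as *top1*, and the five
most populated centroids as the *top5* candidate set. Restraint energies
re-evaluated on the ensemble provide an orthogonal, reference-free ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .conformation import Conformation
from .cg_sampler import RunResult
from .restraints import RestraintCollection, SelectionRecord, select_active

__all__ = [
    "ClusterResult",
    "FunnelProfile",
    "ViolationReport",
    "rmsd",
    "collect_frames",
    "cluster_ensemble",
    "top_predictions",
    "funneling_profile",
    "lowest_restraint_energy_frame",
    "violation_report",
]


def rmsd(a: Conformation | np.ndarray, b: Conformation | np.ndarray, superpose: bool = True) -> float:
    """Cα RMSD in Å; optimal-rotation (Kabsch) superposition by default."""
    xa = a.coords if isinstance(a, Conformation) else np.asarray(a, float)
    xb = b.coords if isinstance(b, Conformation) else np.asarray(b, float)
    if xa.shape != xb.shape:
        raise ValueError(f"length mismatch: {xa.shape} vs {xb.shape}")
    if not superpose:
        return float(np.sqrt(((xa - xb) ** 2).sum(axis=1).mean()))
    return _kabsch_rmsd(xa, xb)


def _kabsch_rmsd(xa: np.ndarray, xb: np.ndarray) -> float:
    pa = xa - xa.mean(axis=0)
    pb = xb - xb.mean(axis=0)
    h = pb.T @ pa
    u, s, vt = np.linalg.svd(h)
    # proper rotation: flip the smallest singular vector if det < 0
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.diag([1.0, 1.0, d])
    rot = u @ flip @ vt
    diff = pb @ rot - pa
    return float(np.sqrt((diff * diff).sum(axis=1).mean()))


@dataclass
class FrameSet:
    """Frames pooled for clustering, with their (replica, frame) origin."""

    coords: np.ndarray  # (m, n_residues, 3)
    origin: list[tuple[int, int]]
    sequence: str = ""

    def __len__(self) -> int:
        return len(self.coords)


def collect_frames(
    run: RunResult,
    n_low_replicas: int = 5,
    fraction: tuple[float, float] = (0.5, 1.0),
) -> FrameSet:
    """Pool frames from the lowest replicas, keeping only the stated
    fraction of each series (default: second half, discarding burn-in)."""
    n_low = min(n_low_replicas, run.n_replicas)
    coords, origin = [], []
    for r in range(n_low):
        series = run.frames[r]
        m = len(series)
        lo, hi = int(math.floor(fraction[0] * m)), int(math.ceil(fraction[1] * m))
        for f in range(lo, hi):
            coords.append(series[f])
            origin.append((r, f))
    if not coords:
        raise ValueError("no frames selected")
    return FrameSet(np.array(coords), origin, run.sequence)


@dataclass
class ClusterResult:
    """Ensemble clustering outcome; cluster 0 is the most populated."""

    labels: np.ndarray  # cluster id per frame, relabelled by population
    populations: np.ndarray  # descending
    centroid_frames: np.ndarray  # medoid frame index per cluster

    @property
    def n_clusters(self) -> int:
        return len(self.populations)


def _pairwise_rmsd_condensed(frames: np.ndarray) -> np.ndarray:
    m = len(frames)
    out = np.empty(m * (m - 1) // 2)
    k = 0
    for i in range(m - 1):
        for j in range(i + 1, m):
            out[k] = _kabsch_rmsd(frames[i], frames[j])
            k += 1
    return out


def cluster_ensemble(frames: FrameSet | np.ndarray, cutoff: float = 2.0) -> ClusterResult:
    """Average-linkage agglomerative clustering on pairwise superposed Cα
    RMSD, cutting the dendrogram at ``cutoff`` Å.

    Defaults follow common practice: 1.5 Å for unambiguous (pre-assigned)
    data, 2.0 Å for ambiguous data. The representative of each cluster is
    its medoid (the member minimising summed RMSD to the rest of the
    cluster), so reported predictions are physical conformations.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    x = frames.coords if isinstance(frames, FrameSet) else np.asarray(frames, float)
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    m = len(x)
    if m == 0:
        raise ValueError("need at least one frame")
    if m == 1:
        return ClusterResult(np.zeros(1, int), np.array([1]), np.array([0]))
    condensed = _pairwise_rmsd_condensed(x)
    z = linkage(condensed, method="average")
    raw = fcluster(z, t=cutoff, criterion="distance") - 1
    # relabel by population (descending), ties by lower raw id
    ids, counts = np.unique(raw, return_counts=True)
    order = np.lexsort((ids, -counts))
    remap = {int(ids[o]): new for new, o in enumerate(order)}
    labels = np.array([remap[int(c)] for c in raw])
    populations = counts[order]
    sq = squareform(condensed)
    centroids = np.empty(len(ids), dtype=int)
    for c in range(len(ids)):
        members = np.flatnonzero(labels == c)
        within = sq[np.ix_(members, members)].sum(axis=1)
        centroids[c] = members[int(np.argmin(within))]
    return ClusterResult(labels, populations, centroids)


def top_predictions(cr: ClusterResult, n: int = 5) -> np.ndarray:
    """Centroid frame indices of the n most populated clusters (top1/top5)."""
    if n < 1:
        raise ValueError("n must be ≥ 1")
    return cr.centroid_frames[: min(n, cr.n_clusters)]


@dataclass
class FunnelProfile:
    """Per-replica RMSD-to-reference distributions down the ladder."""

    medians: np.ndarray
    q25: np.ndarray
    q75: np.ndarray
    samples: list[np.ndarray]
    funneled: bool
    threshold: float


def funneling_profile(
    run: RunResult,
    reference: Conformation,
    threshold: float = 4.0,
    tol: float = 1e-9,
) -> FunnelProfile:
    """RMSD distribution per replica and a funneling diagnostic.

    The run is *funneled* when medians are non-increasing descending the
    ladder (from the highest replica index to replica 0) and the bottom
    median is below ``threshold`` Å (default 4 Å).
    """
    samples = []
    for r in range(run.n_replicas):
        vals = np.array([rmsd(f, reference.coords) for f in run.frames[r]])
        samples.append(vals)
    medians = np.array([np.median(s) if len(s) else np.nan for s in samples])
    q25 = np.array([np.percentile(s, 25) if len(s) else np.nan for s in samples])
    q75 = np.array([np.percentile(s, 75) if len(s) else np.nan for s in samples])
    descending = medians[::-1]  # top of ladder first
    funneled = bool(
        np.all(np.diff(descending) <= tol) and medians[0] < threshold
    )
    return FunnelProfile(medians, q25, q75, samples, funneled, threshold)


def lowest_restraint_energy_frame(
    frames: FrameSet | np.ndarray,
    coll: RestraintCollection,
    accuracy: float | None = None,
    sequence: str = "",
) -> tuple[int, float]:
    """Frame index minimising the selected restraint energy, plus that
    energy; ties break to the lowest frame index."""
    x = frames.coords if isinstance(frames, FrameSet) else np.asarray(frames, float)
    seq = frames.sequence if isinstance(frames, FrameSet) else sequence
    coll_eval = coll if accuracy is None else RestraintCollection(coll.groups, accuracy)
    best_i, best_e = 0, math.inf
    for i, coords in enumerate(x):
        rec = select_active(Conformation(coords, seq), coll_eval)
        if rec.total_restraint_energy < best_e:
            best_i, best_e = i, rec.total_restraint_energy
    return best_i, best_e


@dataclass
class ViolationReport:
    """Enforced/satisfied counts and energy along an accuracy grid."""

    accuracy_grid: np.ndarray
    enforced: np.ndarray
    satisfied: np.ndarray
    energy: np.ndarray
    records: list[SelectionRecord]


def violation_report(
    frame: Conformation,
    coll: RestraintCollection,
    accuracy_grid: list[float] | np.ndarray = (0.2, 0.4, 0.6, 0.8, 1.0),
) -> ViolationReport:
    """Post-analysis of one structure at several trust levels.

    Native-like structures tend to stay violation-free as the enforced
    fraction grows (contacts are satisfied synergistically), so the energy
    column's growth rate is a reference-free quality diagnostic.
    """
    grid = np.asarray(accuracy_grid, float)
    if np.any((grid <= 0) | (grid > 1)):
        raise ValueError("accuracy grid values must be in (0, 1]")
    enforced, satisfied, energy, records = [], [], [], []
    c = coll.compiled()
    gmin, _ = c.group_minima(frame.coords, 1.0)
    for a in grid:
        coll_a = RestraintCollection(coll.groups, float(a))
        rec = select_active(frame, coll_a)
        records.append(rec)
        enforced.append(len(rec.active_peak_ids))
        idx = [c.peak_ids.index(pid) for pid in rec.active_peak_ids]
        satisfied.append(int(sum(1 for i in idx if gmin[i] == 0.0)))
        energy.append(rec.total_restraint_energy)
    return ViolationReport(
        grid, np.array(enforced), np.array(satisfied), np.array(energy), records
    )
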