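"""Standard folding protocols: the full-scale ladder grid and the
desk-scale protocol used throughout the examples and tests.

The full protocol grid combines three temperature ranges (300–550,
350–550, 400–550 K) with three force constants (87, 350, 700
kJ·mol⁻¹·nm⁻²) on a 30-replica ladder with the geometric/plateau schedule;
the preferred protocol is 400–550 K with k = 350. The desk-scale protocol
shrinks this to 6 replicas at coarse-grained temperatures (the Cα prior's
energy scale is not that of an all-atom force field, so its temperatures
are protocol constants of this model, not full-scale Kelvin values).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import (
    ClusterResult,
    FrameSet,
    cluster_ensemble,
    collect_frames,
    rmsd,
    top_predictions,
)
from .cg_sampler import LadderSchedule, PriorParams, RunResult, build_ladder, run_remd
from .conformation import Conformation, extended_chain
from .io_formats import Peak
from .restraints import RestraintCollection, build_restraint_collection

__all__ = [
    "FULL_LADDER_GRID",
    "desk_ladder",
    "desk_prior",
    "FoldResult",
    "fold_and_predict",
]

#: the nine-protocol grid of (t_min, t_max, k): three temperature ranges
#: crossed with three force constants.
FULL_LADDER_GRID = [
    (t_min, 550.0, k)
    for t_min in (300.0, 350.0, 400.0)
    for k in (87.0, 350.0, 700.0)
]


def desk_ladder(n_replicas: int = 6) -> LadderSchedule:
    """6-replica desk-scale ladder: geometric 120→400 "CG Kelvin" up to the
    mid-ladder plateau, linear force-scalar ramp above it."""
    return build_ladder(
        n_replicas, t_min=120.0, t_max=400.0,
        plateau_index=n_replicas // 2, alpha_exponent=1.0,
    )


def desk_prior(ss_wells: list[tuple[int, float, float, float]] | None = None) -> PriorParams:
    """The coarse-grained prior with optional secondary-structure wells."""
    return PriorParams(ss_bias=ss_wells)


@dataclass
class FoldResult:
    """End-to-end outcome of one desk-scale folding run."""

    run: RunResult
    frames: FrameSet
    clusters: ClusterResult
    top_frames: np.ndarray  # frame indices into frames.coords, by population
    collection: RestraintCollection

    def top_coords(self, rank: int = 0) -> np.ndarray:
        return self.frames.coords[self.top_frames[rank]]

    def top_rmsds(self, reference: Conformation) -> list[float]:
        return [float(rmsd(self.frames.coords[t], reference.coords)) for t in self.top_frames]


def fold_and_predict(
    peaks: list[Peak],
    sequence: str,
    accuracy: float = 1.0,
    k: float = 350.0,
    ss_wells: list[tuple[int, float, float, float]] | None = None,
    ladder: LadderSchedule | None = None,
    n_sweeps: int = 2000,
    seed: int = 0,
    cluster_cutoff: float = 2.0,
    n_top: int = 5,
    n_low_replicas: int = 2,
) -> FoldResult:
    """Fold a chain against a peak list and report clustered predictions.

    This is the standard pipeline: build the restraint collection at the
    requested trust ``accuracy`` and force constant ``k``, run H,T-REMD
    from the extended chain, pool the second half of the lowest replicas,
    cluster at ``cluster_cutoff`` Å, and return the top-population medoids.
    """
    coll = build_restraint_collection(peaks, k=k, accuracy=accuracy)
    ladder = ladder or desk_ladder()
    prior = desk_prior(ss_wells)
    initial = extended_chain(len(sequence), sequence=sequence)
    run = run_remd(
        initial, coll, None, ladder, prior=prior,
        n_sweeps=n_sweeps, exchange_stride=5, save_stride=20, seed=seed,
    )
    frames = collect_frames(run, n_low_replicas=n_low_replicas)
    clusters = cluster_ensemble(frames, cutoff=cluster_cutoff)
    top = top_predictions(clusters, n_top)
    return FoldResult(run, frames, clusters, top, coll)
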