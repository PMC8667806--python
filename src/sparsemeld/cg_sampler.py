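"""Hamiltonian + temperature replica-exchange Monte Carlo on a Cα chain.

The posterior p(x|D) ∝ p(D|x)·p(x) is sampled by a ladder of replicas. The
prior p(x) is a minimal Cα physics model (bonds, a wide bond-angle well,
soft-sphere excluded volume, optional secondary-structure bias); the
likelihood is the restraint machinery of :mod:`sparsemeld.restraints`. Down
the ladder the temperature decreases geometrically while the restraint
force scalar α ramps from 0 (pure exploration of the prior) to 1 (full
enforcement of the data), so low replicas exploit minima compatible with
the trusted fraction of the peaks and high replicas keep escaping bad
interpretations.

Replicas move by Metropolis Monte Carlo (single-bead displacement,
crankshaft, pivot); neighbouring replicas attempt configuration swaps with
the standard two-Hamiltonian acceptance rule. Restraint selection is part
of the Hamiltonian: evaluating a configuration under another replica's α
re-selects the trusted subset for that α.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .conformation import (
    Conformation,
    bond_angles,
    bond_lengths,
    extended_chain,
    pseudo_dihedrals,
)
from .restraints import (
    RestraintCollection,
    SelectionRecord,
    TorsionRestraintSet,
    likelihood_energy,
    select_active,
)

__all__ = [
    "KB",
    "PriorParams",
    "LadderSchedule",
    "RunResult",
    "build_ladder",
    "prior_energy",
    "mc_sweep",
    "attempt_exchange",
    "run_remd",
]

#: Boltzmann constant in kJ·mol⁻¹·K⁻¹, so temperatures in K pair with
#: force constants in kJ/mol.
KB = 0.008314


@dataclass
class PriorParams:
    """Parameters of the coarse-grained physics prior p(x).

    All terms are penalty wells (zero at their minimum), so the prior
    energy is ≥ 0 by construction. The bond-angle term is a flat-bottom
    well from ``angle_center − angle_halfwidth`` up to 180°, which keeps
    both helical (~90°) and extended (180°) chains penalty-free.
    """

    bond_length: float = 3.8  # Å, virtual Cα–Cα bond
    k_bond: float = 100.0  # kJ·mol⁻¹·Å⁻²
    angle_center: float = 120.0  # degrees
    angle_halfwidth: float = 35.0  # degrees; well = [center−hw, 180]
    k_angle: float = 60.0  # kJ·mol⁻¹·rad⁻²
    excluded_radius: float = 4.0  # Å, soft-sphere diameter for |i−j| ≥ 2
    k_repulsion: float = 20.0  # kJ·mol⁻¹·Å⁻²
    k_chirality: float = 3.0  # kJ·mol⁻¹; right-handed pseudo-dihedral preference
    ss_bias: list[tuple[int, float, float, float]] | None = None
    # ss_bias entries: (residue, pseudo-dihedral center °, halfwidth °, k kJ·mol⁻¹·rad⁻²)

    def __post_init__(self) -> None:
        if min(self.k_bond, self.k_angle, self.k_repulsion) < 0:
            raise ValueError("force constants must be ≥ 0")


def prior_energy(conf: Conformation | np.ndarray, p: PriorParams) -> float:
    """Energy of the physics prior; 0 for an ideal clash-free chain."""
    coords = conf.coords if isinstance(conf, Conformation) else np.asarray(conf, float)
    if len(coords) < 2:
        raise ValueError("need at least 2 beads")
    e = 0.0
    # bonds
    b = bond_lengths(coords)
    e += 0.5 * p.k_bond * float(((b - p.bond_length) ** 2).sum())
    # angles: flat bottom [center − hw, 180]
    if len(coords) >= 3:
        ang = bond_angles(coords)
        lo = p.angle_center - p.angle_halfwidth
        viol = np.radians(np.maximum(0.0, lo - ang))
        e += 0.5 * p.k_angle * float((viol * viol).sum())
    # soft-sphere repulsion on |i−j| ≥ 2 pairs
    n = len(coords)
    if n >= 3 and p.k_repulsion > 0:
        diff = coords[:, None, :] - coords[None, :, :]
        d2 = (diff * diff).sum(axis=-1)
        iu = np.triu_indices(n, k=2)
        d = np.sqrt(d2[iu])
        over = np.maximum(0.0, p.excluded_radius - d)
        e += 0.5 * p.k_repulsion * float((over * over).sum())
    # chirality: L-amino-acid chains trace right-handed locally, which a
    # distance-only model cannot see (mirror images satisfy every distance
    # bound). Penalise negative pseudo-dihedrals smoothly: zero for
    # θ ∈ [0°, 180°] and at ±180°, maximal at θ = −90°.
    if p.k_chirality > 0 and n >= 4:
        dihs = np.radians(pseudo_dihedrals(coords))
        neg = np.maximum(0.0, -np.sin(dihs))
        e += 0.5 * p.k_chirality * float((neg * neg).sum())
    # optional secondary-structure pseudo-dihedral bias
    if p.ss_bias and n >= 4:
        dihs = pseudo_dihedrals(coords)
        for res, center, hw, k in p.ss_bias:
            if 2 <= res <= n - 2:
                dtheta = (dihs[res - 2] - center + 180.0) % 360.0 - 180.0
                viol = math.radians(max(0.0, abs(dtheta) - hw))
                e += 0.5 * k * viol * viol
    return e


# ---------------------------------------------------------------------------
# replica ladder


@dataclass
class LadderSchedule:
    """Per-replica temperature (K) and restraint force scalar α ∈ [0, 1]."""

    n_replicas: int
    temperature: np.ndarray
    alpha: np.ndarray
    plateau_index: int

    def __post_init__(self) -> None:
        if len(self.temperature) != self.n_replicas or len(self.alpha) != self.n_replicas:
            raise ValueError("schedule arrays must have n_replicas entries")


def build_ladder(
    n: int = 30,
    t_min: float = 400.0,
    t_max: float = 550.0,
    plateau_index: int = 12,
    alpha_exponent: float = 2.0,
) -> LadderSchedule:
    """Geometric temperature ramp up to the plateau replica, constant above;
    α is 1 up to the plateau and ramps nonlinearly to 0 at the top replica.

    T(i) = t_min·(t_max/t_min)^(min(i, plateau)/plateau);
    α(i) = 1 for i ≤ plateau, else (1 − (i − plateau)/(n − 1 − plateau))^q.
    """
    if n < 2:
        raise ValueError("need at least 2 replicas")
    if not (0 < t_min <= t_max):
        raise ValueError("require 0 < t_min ≤ t_max")
    if not (0 <= plateau_index < n):
        raise ValueError("plateau_index must be in [0, n)")
    i = np.arange(n)
    if plateau_index == 0:
        temperature = np.full(n, t_max, dtype=float)
    else:
        frac = np.minimum(i, plateau_index) / plateau_index
        temperature = t_min * (t_max / t_min) ** frac
    if plateau_index >= n - 1:
        alpha = np.ones(n)
    else:
        ramp = 1.0 - (i - plateau_index) / (n - 1 - plateau_index)
        alpha = np.where(i <= plateau_index, 1.0, np.clip(ramp, 0.0, 1.0) ** alpha_exponent)
    return LadderSchedule(n, temperature, alpha, plateau_index)


# ---------------------------------------------------------------------------
# Monte Carlo moves

#: default move mixture: (cumulative probability, kind); segment moves
#: (crankshaft of a whole internal stretch) mix compact states efficiently,
#: pivots mix extended ones.
_P_DISPLACE = 0.35
_P_CRANK = 0.65  # cumulative
_P_SEGMENT = 0.85  # cumulative
_MAX_DISPLACE = 0.35  # Å
_MAX_CRANK = math.radians(60.0)
_MAX_SEGMENT = math.radians(30.0)
_MAX_PIVOT = math.radians(25.0)


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def _propose(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Symmetric proposal: bead displacement, crankshaft (single bead or
    whole segment), or pivot."""
    n = len(coords)
    u = rng.random()
    new = coords.copy()
    if u < _P_DISPLACE or n < 3:
        i = int(rng.integers(n))
        new[i] += rng.normal(0.0, _MAX_DISPLACE, size=3)
    elif u < _P_CRANK or n < 4:
        i = int(rng.integers(1, n - 1))
        axis = coords[i + 1] - coords[i - 1]
        if np.linalg.norm(axis) < 1e-9:
            new[i] += rng.normal(0.0, _MAX_DISPLACE, size=3)
        else:
            ang = rng.uniform(-_MAX_CRANK, _MAX_CRANK)
            rot = _rotation_matrix(axis, ang)
            new[i] = coords[i - 1] + rot @ (coords[i] - coords[i - 1])
    elif u < _P_SEGMENT and n >= 5:
        # rotate interior beads i+1 … j−1 about the i→j axis: bonds at both
        # hinges are preserved, so compact states mix without clash cascades
        i = int(rng.integers(0, n - 3))
        j = int(rng.integers(i + 2, n))
        axis = coords[j] - coords[i]
        if np.linalg.norm(axis) < 1e-9:
            k = int(rng.integers(n))
            new[k] += rng.normal(0.0, _MAX_DISPLACE, size=3)
        else:
            ang = rng.uniform(-_MAX_SEGMENT, _MAX_SEGMENT)
            rot = _rotation_matrix(axis, ang)
            seg = coords[i + 1 : j] - coords[i]
            new[i + 1 : j] = coords[i] + seg @ rot.T
    else:
        i = int(rng.integers(1, n - 1))
        axis = rng.normal(size=3)
        while np.linalg.norm(axis) < 1e-12:
            axis = rng.normal(size=3)
        ang = rng.uniform(-_MAX_PIVOT, _MAX_PIVOT)
        rot = _rotation_matrix(axis, ang)
        if rng.random() < 0.5:  # rotate tail
            new[i + 1 :] = coords[i] + (coords[i + 1 :] - coords[i]) @ rot.T
        else:  # rotate head
            new[:i] = coords[i] + (coords[:i] - coords[i]) @ rot.T
    return new


def mc_sweep(
    state: Conformation,
    energy: Callable[[np.ndarray], float],
    temperature: float,
    rng: np.random.Generator,
    n_moves: int | None = None,
    current_energy: float | None = None,
) -> tuple[Conformation, float]:
    """One Metropolis sweep (default: one attempted move per bead).

    ``energy`` maps a coordinate array to kJ/mol. Each proposed move is
    accepted with min(1, exp(−ΔE/kT)); all three move types are symmetric,
    so detailed balance holds per move. Returns the new conformation and
    its energy.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    coords = state.coords.copy()
    e = energy(coords) if current_energy is None else current_energy
    beta = 1.0 / (KB * temperature)
    n_moves = n_moves if n_moves is not None else len(coords)
    for _ in range(n_moves):
        cand = _propose(coords, rng)
        e_new = energy(cand)
        de = e_new - e
        if de <= 0.0 or rng.random() < math.exp(-beta * de):
            coords, e = cand, e_new
    return Conformation(coords, state.sequence), e


# ---------------------------------------------------------------------------
# replica exchange


def _replica_energy_fn(
    coll: RestraintCollection | None,
    tors: TorsionRestraintSet | None,
    prior: PriorParams,
    alpha: float,
) -> Callable[[np.ndarray], float]:
    compiled = coll.compiled() if (coll is not None and coll.groups) else None

    def energy(coords: np.ndarray) -> float:
        e = prior_energy(coords, prior)
        if alpha > 0.0:
            if compiled is not None:
                e += compiled.active_energy(coords, alpha)
            if tors is not None:
                e += _torsion_fast(coords, tors, alpha)
        return e

    return energy


def _torsion_fast(coords: np.ndarray, tors: TorsionRestraintSet, scale: float) -> float:
    from .restraints import torsion_energy

    return torsion_energy(Conformation(coords), tors, scale)


def attempt_exchange(
    i: int,
    j: int,
    states: list[Conformation],
    ladder: LadderSchedule,
    energies: Sequence[Callable[[np.ndarray], float]],
    rng: np.random.Generator,
) -> bool:
    """Attempt a swap between neighbour replicas i and j = i+1.

    Accepts with min(1, exp(−Δ)), Δ = β_i[U_i(x_j) − U_i(x_i)] +
    β_j[U_j(x_i) − U_j(x_j)], where U_k evaluates the full posterior energy
    under replica k's force scalar (restraint selection recomputed for the
    foreign configuration). On acceptance the configurations swap in place.
    """
    if j != i + 1:
        raise ValueError("only neighbour exchanges (j = i + 1) are supported")
    bi = 1.0 / (KB * ladder.temperature[i])
    bj = 1.0 / (KB * ladder.temperature[j])
    xi, xj = states[i].coords, states[j].coords
    delta = bi * (energies[i](xj) - energies[i](xi)) + bj * (energies[j](xi) - energies[j](xj))
    if delta <= 0.0 or rng.random() < math.exp(-delta):
        states[i], states[j] = states[j], states[i]
        return True
    return False


@dataclass
class RunResult:
    """Thinned trajectories, per-frame restraint selections and exchange
    statistics of one replica-exchange run."""

    frames: list[np.ndarray]  # per replica: (n_saved, n_residues, 3)
    selection_log: list[list[SelectionRecord]]  # per replica, per saved frame
    exchange_acceptance: np.ndarray  # per neighbour pair
    seed: int
    sequence: str = ""
    ladder: LadderSchedule | None = None

    @property
    def n_replicas(self) -> int:
        return len(self.frames)

    def replica_frames(self, i: int) -> np.ndarray:
        return self.frames[i]


def run_remd(
    initial: Conformation,
    coll: RestraintCollection | None,
    tors: TorsionRestraintSet | None,
    ladder: LadderSchedule,
    prior: PriorParams | None = None,
    n_sweeps: int = 2000,
    exchange_stride: int = 10,
    save_stride: int = 10,
    seed: int = 0,
    moves_per_sweep: int | None = None,
) -> RunResult:
    """Run H,T-REMD from ``initial`` (by default the extended chain).

    A sweep is ``moves_per_sweep`` attempted Metropolis moves (default
    twice the chain length: roughly one local and one collective attempt
    per bead). Restraint selection is implicit in every energy evaluation
    (the trusted subset is re-derived from the instantaneous structure).
    Neighbour swaps are attempted on alternating even/odd pairs every
    ``exchange_stride`` sweeps; frames and selection records are saved
    every ``save_stride`` sweeps. Fully reproducible given ``seed``.

    The hot loop runs through compiled kernels when only distance
    restraints are present; with torsion restraints it falls back to the
    reference Python path.
    """
    prior = prior or PriorParams()
    rng = np.random.default_rng(seed)
    n_rep = ladder.n_replicas
    n_moves = moves_per_sweep if moves_per_sweep is not None else 2 * len(initial)
    states = [initial.copy() for _ in range(n_rep)]

    fast = tors is None
    if fast:
        from ._kernels import PriorArrays, posterior_energy, sweep_kernel

        pa = PriorArrays(prior).as_tuple()
        if coll is not None and coll.groups:
            c = coll.compiled()
            like = (c.idx_i, c.idx_j, c.d_low, c.d_high, c.k_a, c.onset,
                    c.group_starts, c.n_active)
        else:
            like = (np.empty(0, np.intp), np.empty(0, np.intp), np.empty(0),
                    np.empty(0), np.empty(0), np.empty(0), np.empty(0, np.intp), 0)

        def make_fn(alpha: float):
            def energy(coords: np.ndarray) -> float:
                return posterior_energy(coords, alpha, *pa, *like)

            return energy

        energy_fns = [make_fn(float(ladder.alpha[r])) for r in range(n_rep)]
    else:
        energy_fns = [
            _replica_energy_fn(coll, tors, prior, float(ladder.alpha[r]))
            for r in range(n_rep)
        ]
    cached = [energy_fns[r](states[r].coords) for r in range(n_rep)]

    frames: list[list[np.ndarray]] = [[] for _ in range(n_rep)]
    sel_log: list[list[SelectionRecord]] = [[] for _ in range(n_rep)]
    attempts = np.zeros(max(n_rep - 1, 1))
    accepts = np.zeros(max(n_rep - 1, 1))

    for sweep in range(1, n_sweeps + 1):
        for r in range(n_rep):
            if fast:
                kt = KB * float(ladder.temperature[r])
                coords, e = sweep_kernel(
                    states[r].coords, cached[r], kt, n_moves, rng,
                    _P_DISPLACE, _P_CRANK, _P_SEGMENT,
                    _MAX_DISPLACE, _MAX_CRANK, _MAX_SEGMENT, _MAX_PIVOT,
                    float(ladder.alpha[r]), *pa, *like,
                )
                states[r] = Conformation(coords, states[r].sequence)
                cached[r] = e
            else:
                states[r], cached[r] = mc_sweep(
                    states[r], energy_fns[r], float(ladder.temperature[r]), rng,
                    n_moves=n_moves, current_energy=cached[r],
                )
            if not math.isfinite(cached[r]):
                raise RuntimeError(
                    f"non-finite energy at replica {r}, sweep {sweep}"
                )
        if n_rep > 1 and sweep % exchange_stride == 0:
            parity = (sweep // exchange_stride) % 2
            for i in range(parity, n_rep - 1, 2):
                attempts[i] += 1
                if attempt_exchange(i, i + 1, states, ladder, energy_fns, rng):
                    accepts[i] += 1
                    cached[i] = energy_fns[i](states[i].coords)
                    cached[i + 1] = energy_fns[i + 1](states[i + 1].coords)
        if sweep % save_stride == 0:
            for r in range(n_rep):
                frames[r].append(states[r].coords.copy())
                if coll is not None and coll.groups:
                    sel_log[r].append(
                        select_active(states[r], coll, float(ladder.alpha[r]))
                    )

    acceptance = np.divide(
        accepts, attempts, out=np.ones_like(accepts), where=attempts > 0
    )
    return RunResult(
        frames=[np.array(f) if f else np.empty((0, len(initial), 3)) for f in frames],
        selection_log=sel_log,
        exchange_acceptance=acceptance[: max(n_rep - 1, 0)],
        seed=seed,
        sequence=initial.sequence,
        ladder=ladder,
    )
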