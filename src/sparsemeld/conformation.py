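"""Coarse-grained chain representation and geometry primitives.

The sampler and the restraint machinery both work on a Cα-bead chain: one
bead per residue, coordinates in Å. This module holds the shared container
and the small geometric kernels (distances, pseudo bond angles, pseudo
dihedrals, chain construction from internal coordinates) that everything
else builds on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Conformation",
    "pairwise_distances",
    "bond_lengths",
    "bond_angles",
    "pseudo_dihedrals",
    "chain_from_internal",
    "extended_chain",
    "radius_of_gyration",
]


@dataclass
class Conformation:
    """A Cα chain: ``coords[i]`` is the position of residue ``i+1`` in Å.

    Parameters
    ----------
    coords : (n, 3) float array
        Cα positions in Å.
    sequence : str
        One-letter residue codes, one per bead.
    """

    coords: np.ndarray
    sequence: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.sequence and len(self.sequence) != len(self.coords):
            raise ValueError(
                f"sequence length {len(self.sequence)} != {len(self.coords)} beads"
            )
        if not self.sequence:
            self.sequence = "A" * len(self.coords)

    def __len__(self) -> int:
        return len(self.coords)

    def copy(self) -> "Conformation":
        return Conformation(self.coords.copy(), self.sequence)


def pairwise_distances(coords: np.ndarray) -> np.ndarray:
    d = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((d * d).sum(axis=-1))


def bond_lengths(coords: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.diff(coords, axis=0), axis=1)


def bond_angles(coords: np.ndarray) -> np.ndarray:
    """Pseudo bond angle at each internal bead, degrees in [0, 180]."""
    u = coords[:-2] - coords[1:-1]
    v = coords[2:] - coords[1:-1]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    c = (u * v).sum(axis=1) / (nu * nv)
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def pseudo_dihedrals(coords: np.ndarray) -> np.ndarray:
    """Cα pseudo-dihedral for each quadruple (i, i+1, i+2, i+3), degrees in (−180, 180]."""
    b0 = coords[1:-2] - coords[:-3]
    b1 = coords[2:-1] - coords[1:-2]
    b2 = coords[3:] - coords[2:-1]
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=1, keepdims=True))
    x = (n1 * n2).sum(axis=1)
    y = (m1 * n2).sum(axis=1)
    ang = np.degrees(np.arctan2(y, x))
    # normalise −180 → +180 so angles live in (−180, 180]
    ang[ang <= -180.0] += 360.0
    return ang


def chain_from_internal(
    bonds: np.ndarray, angles_deg: np.ndarray, dihedrals_deg: np.ndarray
) -> np.ndarray:
    """Build Cartesian bead positions from internal coordinates (NeRF).

    ``bonds`` has length n−1, ``angles_deg`` n−2, ``dihedrals_deg`` n−3.
    """
    bonds = np.asarray(bonds, float)
    angles = np.radians(np.asarray(angles_deg, float))
    dihedrals = np.radians(np.asarray(dihedrals_deg, float))
    n = len(bonds) + 1
    coords = np.zeros((n, 3))
    if n > 1:
        coords[1] = [bonds[0], 0.0, 0.0]
    if n > 2:
        th = np.pi - angles[0]
        coords[2] = coords[1] + bonds[1] * np.array([np.cos(th), np.sin(th), 0.0])
    for i in range(3, n):
        b, th, ph = bonds[i - 1], angles[i - 2], dihedrals[i - 3]
        # sign convention chosen so pseudo_dihedrals() recovers ``ph``
        d = np.array(
            [
                -b * np.cos(th),
                b * np.sin(th) * np.cos(ph),
                -b * np.sin(th) * np.sin(ph),
            ]
        )
        bc = coords[i - 1] - coords[i - 2]
        bc /= np.linalg.norm(bc)
        ab = coords[i - 2] - coords[i - 3]
        nrm = np.cross(ab, bc)
        nrm /= np.linalg.norm(nrm)
        m = np.column_stack([bc, np.cross(nrm, bc), nrm])
        coords[i] = coords[i - 1] + m @ d
    return coords


def extended_chain(n: int, bond_length: float = 3.8, sequence: str = "") -> Conformation:
    """Straight chain along x at ``bond_length`` spacing — the standard start state."""
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * bond_length
    return Conformation(coords, sequence or "A" * n)


def radius_of_gyration(coords: np.ndarray) -> float:
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c * c).sum(axis=1).mean()))
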