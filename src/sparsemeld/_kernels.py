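"""Numba-compiled hot loops for the replica-exchange sampler.

These kernels mirror the reference numpy implementations in
:mod:`sparsemeld.cg_sampler` and :mod:`sparsemeld.restraints` exactly (the
test suite asserts agreement); they exist only because the sampler
evaluates the posterior energy millions of times per run.

Because the restraint selection (per-group argmin and the trusted-subset
cut) is invariant under a uniform scaling of all force constants, the
likelihood at force scalar α equals α times the likelihood at α = 1; the
kernels exploit that and compute the unscaled energy once.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["posterior_energy", "sweep_kernel", "PriorArrays"]


@njit(cache=True)
def _prior_energy_kernel(
    coords,
    bond_length,
    k_bond,
    angle_lo_deg,
    k_angle,
    excluded_radius,
    k_repulsion,
    k_chirality,
    ss_res,
    ss_center,
    ss_hw,
    ss_k,
):
    n = coords.shape[0]
    e = 0.0
    # bonds
    for i in range(n - 1):
        dx = coords[i + 1, 0] - coords[i, 0]
        dy = coords[i + 1, 1] - coords[i, 1]
        dz = coords[i + 1, 2] - coords[i, 2]
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        e += 0.5 * k_bond * (d - bond_length) ** 2
    # bond angles: flat-bottom well [angle_lo, 180]
    for i in range(1, n - 1):
        ux = coords[i - 1, 0] - coords[i, 0]
        uy = coords[i - 1, 1] - coords[i, 1]
        uz = coords[i - 1, 2] - coords[i, 2]
        vx = coords[i + 1, 0] - coords[i, 0]
        vy = coords[i + 1, 1] - coords[i, 1]
        vz = coords[i + 1, 2] - coords[i, 2]
        nu = math.sqrt(ux * ux + uy * uy + uz * uz)
        nv = math.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        ang = math.degrees(math.acos(c))
        if ang < angle_lo_deg:
            viol = math.radians(angle_lo_deg - ang)
            e += 0.5 * k_angle * viol * viol
    # soft-sphere repulsion, |i−j| ≥ 2
    if k_repulsion > 0.0:
        for i in range(n - 2):
            for j in range(i + 2, n):
                dx = coords[i, 0] - coords[j, 0]
                dy = coords[i, 1] - coords[j, 1]
                dz = coords[i, 2] - coords[j, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < excluded_radius * excluded_radius:
                    over = excluded_radius - math.sqrt(d2)
                    e += 0.5 * k_repulsion * over * over
    # chirality + optional ss bias need pseudo-dihedrals
    if (k_chirality > 0.0 or ss_res.shape[0] > 0) and n >= 4:
        for d_idx in range(n - 3):
            theta = _dihedral(coords, d_idx)
            if k_chirality > 0.0:
                s = math.sin(math.radians(theta))
                if s < 0.0:
                    e += 0.5 * k_chirality * s * s
            for t in range(ss_res.shape[0]):
                if ss_res[t] - 2 == d_idx:
                    dth = (theta - ss_center[t] + 180.0) % 360.0 - 180.0
                    v = abs(dth) - ss_hw[t]
                    if v > 0.0:
                        vr = math.radians(v)
                        e += 0.5 * ss_k[t] * vr * vr
    return e


@njit(cache=True)
def _dihedral(coords, i):
    """Pseudo-dihedral over beads (i, i+1, i+2, i+3), degrees."""
    b0x = coords[i + 1, 0] - coords[i, 0]
    b0y = coords[i + 1, 1] - coords[i, 1]
    b0z = coords[i + 1, 2] - coords[i, 2]
    b1x = coords[i + 2, 0] - coords[i + 1, 0]
    b1y = coords[i + 2, 1] - coords[i + 1, 1]
    b1z = coords[i + 2, 2] - coords[i + 1, 2]
    b2x = coords[i + 3, 0] - coords[i + 2, 0]
    b2y = coords[i + 3, 1] - coords[i + 2, 1]
    b2z = coords[i + 3, 2] - coords[i + 2, 2]
    n1x = b0y * b1z - b0z * b1y
    n1y = b0z * b1x - b0x * b1z
    n1z = b0x * b1y - b0y * b1x
    n2x = b1y * b2z - b1z * b2y
    n2y = b1z * b2x - b1x * b2z
    n2z = b1x * b2y - b1y * b2x
    nb1 = math.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
    m1x = (n1y * b1z - n1z * b1y) / nb1
    m1y = (n1z * b1x - n1x * b1z) / nb1
    m1z = (n1x * b1y - n1y * b1x) / nb1
    x = n1x * n2x + n1y * n2y + n1z * n2z
    y = m1x * n2x + m1y * n2y + m1z * n2z
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


@njit(cache=True)
def _likelihood_unscaled(
    coords, idx_i, idx_j, d_low, d_high, k_a, onset, group_starts, n_active
):
    n_groups = group_starts.shape[0]
    n_members = idx_i.shape[0]
    gmin = np.empty(n_groups)
    for g in range(n_groups):
        start = group_starts[g]
        end = group_starts[g + 1] if g + 1 < n_groups else n_members
        best = 1e300
        for m in range(start, end):
            a = idx_i[m]
            b = idx_j[m]
            dx = coords[a, 0] - coords[b, 0]
            dy = coords[a, 1] - coords[b, 1]
            dz = coords[a, 2] - coords[b, 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            delta = 0.0
            if r > d_high[m]:
                delta = r - d_high[m]
            elif r < d_low[m]:
                delta = d_low[m] - r
            if delta <= onset[m]:
                em = 0.5 * k_a[m] * delta * delta
            else:
                em = 0.5 * k_a[m] * onset[m] * onset[m] + k_a[m] * onset[m] * (
                    delta - onset[m]
                )
            if em < best:
                best = em
        gmin[g] = best
    if n_active >= n_groups:
        return gmin.sum()
    part = np.partition(gmin, n_active - 1)
    total = 0.0
    for g in range(n_active):
        total += part[g]
    return total


@njit(cache=True)
def posterior_energy(
    coords,
    alpha,
    # prior
    bond_length,
    k_bond,
    angle_lo_deg,
    k_angle,
    excluded_radius,
    k_repulsion,
    k_chirality,
    ss_res,
    ss_center,
    ss_hw,
    ss_k,
    # likelihood
    idx_i,
    idx_j,
    d_low,
    d_high,
    k_a,
    onset,
    group_starts,
    n_active,
):
    e = _prior_energy_kernel(
        coords, bond_length, k_bond, angle_lo_deg, k_angle,
        excluded_radius, k_repulsion, k_chirality, ss_res, ss_center, ss_hw, ss_k,
    )
    if alpha > 0.0 and idx_i.shape[0] > 0:
        e += alpha * _likelihood_unscaled(
            coords, idx_i, idx_j, d_low, d_high, k_a, onset, group_starts, n_active
        )
    return e


@njit(cache=True)
def _rotate_about_axis(out, coords, lo, hi, px, py, pz, ax, ay, az, ang):
    """Rotate beads [lo, hi) about the axis (ax,ay,az) through point p."""
    norm = math.sqrt(ax * ax + ay * ay + az * az)
    ax /= norm
    ay /= norm
    az /= norm
    c = math.cos(ang)
    s = math.sin(ang)
    C = 1.0 - c
    r00 = c + ax * ax * C
    r01 = ax * ay * C - az * s
    r02 = ax * az * C + ay * s
    r10 = ay * ax * C + az * s
    r11 = c + ay * ay * C
    r12 = ay * az * C - ax * s
    r20 = az * ax * C - ay * s
    r21 = az * ay * C + ax * s
    r22 = c + az * az * C
    for i in range(lo, hi):
        x = coords[i, 0] - px
        y = coords[i, 1] - py
        z = coords[i, 2] - pz
        out[i, 0] = px + r00 * x + r01 * y + r02 * z
        out[i, 1] = py + r10 * x + r11 * y + r12 * z
        out[i, 2] = pz + r20 * x + r21 * y + r22 * z


@njit(cache=True)
def sweep_kernel(
    coords,
    e0,
    kt,
    n_moves,
    rng,
    # move amplitudes
    p_displace,
    p_crank,
    p_segment,
    max_displace,
    max_crank,
    max_segment,
    max_pivot,
    # model (same layout as posterior_energy)
    alpha,
    bond_length,
    k_bond,
    angle_lo_deg,
    k_angle,
    excluded_radius,
    k_repulsion,
    k_chirality,
    ss_res,
    ss_center,
    ss_hw,
    ss_k,
    idx_i,
    idx_j,
    d_low,
    d_high,
    k_a,
    onset,
    group_starts,
    n_active,
):
    """One Metropolis sweep; mutates/replaces coords, returns final energy."""
    n = coords.shape[0]
    e = e0
    cand = coords.copy()
    for _ in range(n_moves):
        # refresh proposal buffer
        for i in range(n):
            cand[i, 0] = coords[i, 0]
            cand[i, 1] = coords[i, 1]
            cand[i, 2] = coords[i, 2]
        u = rng.random()
        if u < p_displace or n < 3:
            i = int(rng.integers(0, n))
            cand[i, 0] += rng.normal(0.0, max_displace)
            cand[i, 1] += rng.normal(0.0, max_displace)
            cand[i, 2] += rng.normal(0.0, max_displace)
        elif u < p_crank or n < 4:
            i = int(rng.integers(1, n - 1))
            ax = coords[i + 1, 0] - coords[i - 1, 0]
            ay = coords[i + 1, 1] - coords[i - 1, 1]
            az = coords[i + 1, 2] - coords[i - 1, 2]
            if ax * ax + ay * ay + az * az < 1e-18:
                cand[i, 0] += rng.normal(0.0, max_displace)
                cand[i, 1] += rng.normal(0.0, max_displace)
                cand[i, 2] += rng.normal(0.0, max_displace)
            else:
                ang = rng.uniform(-max_crank, max_crank)
                _rotate_about_axis(
                    cand, coords, i, i + 1,
                    coords[i - 1, 0], coords[i - 1, 1], coords[i - 1, 2],
                    ax, ay, az, ang,
                )
        elif u < p_segment and n >= 5:
            i = int(rng.integers(0, n - 3))
            j = int(rng.integers(i + 2, n))
            ax = coords[j, 0] - coords[i, 0]
            ay = coords[j, 1] - coords[i, 1]
            az = coords[j, 2] - coords[i, 2]
            if ax * ax + ay * ay + az * az < 1e-18:
                k_b = int(rng.integers(0, n))
                cand[k_b, 0] += rng.normal(0.0, max_displace)
                cand[k_b, 1] += rng.normal(0.0, max_displace)
                cand[k_b, 2] += rng.normal(0.0, max_displace)
            else:
                ang = rng.uniform(-max_segment, max_segment)
                _rotate_about_axis(
                    cand, coords, i + 1, j,
                    coords[i, 0], coords[i, 1], coords[i, 2],
                    ax, ay, az, ang,
                )
        else:
            i = int(rng.integers(1, n - 1))
            ax = rng.normal(0.0, 1.0)
            ay = rng.normal(0.0, 1.0)
            az = rng.normal(0.0, 1.0)
            while ax * ax + ay * ay + az * az < 1e-24:
                ax = rng.normal(0.0, 1.0)
                ay = rng.normal(0.0, 1.0)
                az = rng.normal(0.0, 1.0)
            ang = rng.uniform(-max_pivot, max_pivot)
            if rng.random() < 0.5:
                _rotate_about_axis(
                    cand, coords, i + 1, n,
                    coords[i, 0], coords[i, 1], coords[i, 2], ax, ay, az, ang,
                )
            else:
                _rotate_about_axis(
                    cand, coords, 0, i,
                    coords[i, 0], coords[i, 1], coords[i, 2], ax, ay, az, ang,
                )
        e_new = posterior_energy(
            cand, alpha, bond_length, k_bond, angle_lo_deg, k_angle,
            excluded_radius, k_repulsion, k_chirality, ss_res, ss_center, ss_hw, ss_k,
            idx_i, idx_j, d_low, d_high, k_a, onset, group_starts, n_active,
        )
        de = e_new - e
        if de <= 0.0 or rng.random() < math.exp(-de / kt):
            tmp = coords
            coords = cand
            cand = tmp
            e = e_new
    return coords, e


class PriorArrays:
    """Flattened PriorParams + optional ss-bias arrays for the kernels."""

    def __init__(self, prior) -> None:
        self.bond_length = float(prior.bond_length)
        self.k_bond = float(prior.k_bond)
        self.angle_lo_deg = float(prior.angle_center - prior.angle_halfwidth)
        self.k_angle = float(prior.k_angle)
        self.excluded_radius = float(prior.excluded_radius)
        self.k_repulsion = float(prior.k_repulsion)
        self.k_chirality = float(prior.k_chirality)
        bias = prior.ss_bias or []
        self.ss_res = np.array([b[0] for b in bias], dtype=np.intp)
        self.ss_center = np.array([b[1] for b in bias], dtype=np.float64)
        self.ss_hw = np.array([b[2] for b in bias], dtype=np.float64)
        self.ss_k = np.array([b[3] for b in bias], dtype=np.float64)

    def as_tuple(self):
        return (
            self.bond_length, self.k_bond, self.angle_lo_deg, self.k_angle,
            self.excluded_radius, self.k_repulsion, self.k_chirality,
            self.ss_res, self.ss_center, self.ss_hw, self.ss_k,
        )
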