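import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sparsemeld.conformation import Conformation, chain_from_internal
from sparsemeld.io_formats import Interpretation, Peak, TorsionPrediction
from sparsemeld.restraints import (
    FlatBottomParams,
    RestraintCollection,
    RestraintGroup,
    TorsionRestraintSet,
    build_restraint_collection,
    flat_bottom_energy,
    group_energy,
    likelihood_energy,
    select_active,
    torsion_energy,
)


class TestFlatBottomEnergy:
    @pytest.mark.parametrize(
        "k,expected", [(87.0, 0.435), (350.0, 1.75), (700.0, 3.5)]
    )
    def test_one_angstrom_violation_penalties(self, k, expected):
        """The three protocol force constants (kJ·mol⁻¹·nm⁻²) cost exactly
        0.435 / 1.75 / 3.5 kJ/mol at a 1 Å violation of the bound."""
        p = FlatBottomParams(k=k, d_low=0.0, d_high=6.0)
        assert flat_bottom_energy(7.0, p) == pytest.approx(expected, abs=1e-12)

    def test_zero_inside_the_flat_bottom(self):
        p = FlatBottomParams(k=350.0, d_low=2.0, d_high=6.0)
        for r in (2.0, 3.7, 6.0):
            assert flat_bottom_energy(r, p) == 0.0

    def test_lower_wall_is_symmetric(self):
        p = FlatBottomParams(k=350.0, d_low=3.0, d_high=6.0)
        assert flat_bottom_energy(2.0, p) == pytest.approx(
            flat_bottom_energy(7.0, p)
        )

    def test_continuous_and_differentiable_at_linear_switch(self):
        p = FlatBottomParams(k=350.0, d_high=6.0, linear_onset=2.0)
        r0 = 8.0  # exactly at the switch
        eps = 1e-6
        e_lo = flat_bottom_energy(r0 - eps, p)
        e_hi = flat_bottom_energy(r0 + eps, p)
        assert e_hi - e_lo == pytest.approx(0.0, abs=1e-4)
        slope_lo = (flat_bottom_energy(r0, p) - flat_bottom_energy(r0 - eps, p)) / eps
        slope_hi = (flat_bottom_energy(r0 + eps, p) - flat_bottom_energy(r0, p)) / eps
        assert slope_lo == pytest.approx(slope_hi, rel=1e-3)

    def test_linear_tail_slope_is_constant(self):
        p = FlatBottomParams(k=350.0, d_high=6.0, linear_onset=2.0)
        s1 = flat_bottom_energy(10.0, p) - flat_bottom_energy(9.0, p)
        s2 = flat_bottom_energy(12.0, p) - flat_bottom_energy(11.0, p)
        assert s1 == pytest.approx(s2)

    @settings(derandomize=True, deadline=None, max_examples=200)
    @given(
        r=st.floats(0.0, 30.0),
        k=st.floats(0.0, 1000.0),
        d_low=st.floats(0.0, 4.0),
        width=st.floats(0.0, 6.0),
        onset=st.floats(0.5, 4.0),
    )
    def test_well_properties(self, r, k, d_low, width, onset):
        """Non-negative everywhere; zero exactly inside [d_low, d_high];
        non-decreasing beyond the upper edge."""
        p = FlatBottomParams(k=k, d_low=d_low, d_high=d_low + width, linear_onset=onset)
        e = flat_bottom_energy(r, p)
        assert e >= 0.0
        if d_low <= r <= p.d_high:
            assert e == 0.0
        if r > p.d_high:
            assert flat_bottom_energy(r + 0.5, p) >= e


def _conf(coords):
    return Conformation(np.asarray(coords, float))


def _brute_group_energy(conf, group, scale):
    """Independent evaluation: direct distance + by-hand well arithmetic."""
    best = (math.inf, -1)
    for idx, (it, p) in enumerate(group.restraints):
        r = float(
            np.linalg.norm(
                conf.coords[it.residue_i - 1] - conf.coords[it.residue_j - 1]
            )
        )
        delta = max(0.0, r - p.d_high, p.d_low - r)
        k_a = scale * p.k / 100.0
        if delta <= p.linear_onset:
            e = 0.5 * k_a * delta**2
        else:
            e = 0.5 * k_a * p.linear_onset**2 + k_a * p.linear_onset * (
                delta - p.linear_onset
            )
        if e < best[0]:
            best = (e, idx)
    return best


class TestGroupEnergy:
    def test_minimum_member_selected(self, rng):
        coords = rng.normal(0, 8, (30, 3))
        conf = _conf(coords)
        for _ in range(30):
            members = [
                (
                    Interpretation(
                        int(rng.integers(1, 31)), "CA", int(rng.integers(1, 31)) , "CA",
                        upper_bound=float(rng.uniform(2, 8)),
                    ),
                    FlatBottomParams(k=float(rng.choice([87, 350, 700])), d_high=float(rng.uniform(3, 8))),
                )
                for _ in range(int(rng.integers(1, 21)))
            ]
            g = RestraintGroup("g", members)
            e, idx = group_energy(conf, g, scale=0.7)
            be, bidx = _brute_group_energy(conf, g, 0.7)
            assert e == pytest.approx(be)
            assert idx == bidx  # ties break to lowest member index

    def test_satisfied_member_gives_zero(self):
        conf = _conf([[0, 0, 0], [0, 0, 3], [0, 0, 50]])
        g = RestraintGroup(
            "g",
            [
                (Interpretation(1, "CA", 3, "CA"), FlatBottomParams(k=350, d_high=6.0)),
                (Interpretation(1, "CA", 2, "CA"), FlatBottomParams(k=350, d_high=6.0)),
            ],
        )
        assert group_energy(conf, g) == (0.0, 1)

    def test_unresolvable_members_are_infinite(self):
        conf = _conf([[0, 0, 0], [3, 0, 0]])
        g = RestraintGroup(
            "g",
            [
                (Interpretation(1, "CA", 9, "CA"), FlatBottomParams(k=350)),
                (Interpretation(1, "CA", 2, "CA"), FlatBottomParams(k=350)),
            ],
        )
        assert group_energy(conf, g)[1] == 1
        bad = RestraintGroup("g", [(Interpretation(1, "CA", 9, "CA"), FlatBottomParams(k=350))])
        with pytest.raises(ValueError, match="resolvable"):
            group_energy(conf, bad)


def _random_collection(rng, n_coords, n_groups, max_members, accuracy):
    groups = []
    for gi in range(n_groups):
        members = [
            (
                Interpretation(
                    int(rng.integers(1, n_coords + 1)), "CA",
                    int(rng.integers(1, n_coords + 1)), "CA",
                ),
                FlatBottomParams(k=350.0, d_high=float(rng.uniform(2, 9))),
            )
            for _ in range(int(rng.integers(1, max_members + 1)))
        ]
        groups.append(RestraintGroup(f"g{gi:02d}", members))
    return RestraintCollection(groups, accuracy=accuracy)


def _enumerate_best_subset(conf, coll):
    """Exhaustive oracle: best sum over all choices of ceil(a·N) groups,
    each represented by any one member."""
    minima = [_brute_group_energy(conf, g, 1.0)[0] for g in coll.groups]
    m = coll.n_active
    best = math.inf
    for subset in itertools.combinations(range(len(minima)), m):
        # per-group free member choice: the minimum member is always optimal
        best = min(best, sum(minima[i] for i in subset))
    return best


class TestSelectActive:
    def test_three_group_example(self):
        conf = _conf([[0, 0, 0], [10, 0, 0], [11, 0, 0], [30, 0, 0]])
        groups = [
            RestraintGroup("a", [(Interpretation(2, "CA", 3, "CA"), FlatBottomParams(k=350, d_high=0.76))]),
            RestraintGroup("b", [(Interpretation(2, "CA", 3, "CA"), FlatBottomParams(k=350, d_high=0.465))]),
            RestraintGroup("c", [(Interpretation(1, "CA", 4, "CA"), FlatBottomParams(k=350, d_high=27.734))]),
        ]
        # violations: a: 0.24 → 0.1008; b: 0.535 → 0.5009…; c: 2.266 → ~9
        coll = RestraintCollection(groups, accuracy=2 / 3)
        rec = select_active(conf, coll)
        assert rec.active_peak_ids == {"a", "b"}
        brute = sum(sorted(_brute_group_energy(conf, g, 1.0)[0] for g in groups)[:2])
        assert rec.total_restraint_energy == pytest.approx(brute)

    def test_full_accuracy_activates_all(self, rng):
        conf = _conf(rng.normal(0, 6, (12, 3)))
        coll = _random_collection(rng, 12, 6, 3, accuracy=1.0)
        rec = select_active(conf, coll)
        assert len(rec.active_peak_ids) == 6

    def test_all_satisfied_gives_zero_energy(self):
        conf = _conf([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        coll = build_restraint_collection(
            [Peak("p", [Interpretation(1, "CA", 2, "CA", upper_bound=5.0)])],
            accuracy=1.0,
        )
        assert select_active(conf, coll).total_restraint_energy == 0.0

    def test_matches_exhaustive_enumeration(self, rng):
        """Selection is the global minimum over all one-per-group subsets."""
        for _ in range(40):
            n_groups = int(rng.integers(2, 9))
            acc = float(rng.uniform(0.2, 1.0))
            conf = _conf(rng.normal(0, 7, (10, 3)))
            coll = _random_collection(rng, 10, n_groups, 4, acc)
            rec = select_active(conf, coll)
            assert len(rec.active_peak_ids) == math.ceil(acc * n_groups)
            assert rec.total_restraint_energy == pytest.approx(
                _enumerate_best_subset(conf, coll)
            )

    def test_energy_non_decreasing_in_accuracy(self, rng):
        conf = _conf(rng.normal(0, 7, (10, 3)))
        coll = _random_collection(rng, 10, 7, 3, 1.0)
        energies = [
            select_active(conf, RestraintCollection(coll.groups, a)).total_restraint_energy
            for a in (0.2, 0.4, 0.6, 0.8, 1.0)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(energies, energies[1:]))

    def test_invariant_under_rigid_transforms(self, rng):
        from scipy.spatial.transform import Rotation

        conf = _conf(rng.normal(0, 7, (10, 3)))
        coll = _random_collection(rng, 10, 5, 3, 0.6)
        e0 = select_active(conf, coll).total_restraint_energy
        rot = Rotation.random(rng=42).as_matrix()
        moved = _conf(conf.coords @ rot.T + np.array([5.0, -3.0, 9.0]))
        assert select_active(moved, coll).total_restraint_energy == pytest.approx(e0)


def _helix_conf(n=12):
    return Conformation(
        chain_from_internal(
            np.full(n - 1, 3.8), np.full(n - 2, 89.0), np.full(n - 3, 51.0)
        )
    )


class TestTorsionEnergy:
    def test_inside_well_is_zero(self):
        conf = _helix_conf()
        preds = [TorsionPrediction(r, -63.0, -42.0, 20.0, 20.0) for r in range(2, 8)]
        t = TorsionRestraintSet([(p, 20.0) for p in preds], accuracy=1.0)
        assert torsion_energy(conf, t) == 0.0  # helix matches helix wells

    def test_accuracy_count_rule(self):
        conf = _helix_conf(14)
        # strand predictions on a helix: all violated equally → selection
        # keeps exactly ceil(0.8 × 10) = 8 entries
        preds = [TorsionPrediction(r, -120.0, 130.0, 5.0, 5.0) for r in range(2, 12)]
        t_all = TorsionRestraintSet([(p, 20.0) for p in preds], accuracy=1.0)
        t_80 = TorsionRestraintSet([(p, 20.0) for p in preds], accuracy=0.8)
        assert torsion_energy(conf, t_80) == pytest.approx(
            0.8 * torsion_energy(conf, t_all)
        )

    def test_matches_brute_force_selection(self, rng):
        from sparsemeld.conformation import pseudo_dihedrals
        from sparsemeld.restraints import pseudo_dihedral_center

        conf = _conf(rng.normal(0, 6, (15, 3)))
        preds = [
            TorsionPrediction(
                int(r), float(rng.uniform(-170, 170)), float(rng.uniform(-170, 170)),
                20.0, 25.0,
            )
            for r in rng.integers(2, 14, size=9)
        ]
        t = TorsionRestraintSet([(p, 15.0) for p in preds], accuracy=0.7)
        dihs = pseudo_dihedrals(conf.coords)
        brute = []
        for p in preds:
            mapped = pseudo_dihedral_center(p.phi_center, p.psi_center)
            if mapped is None:
                brute.append(0.0)
                continue
            center, extra = mapped
            theta = dihs[p.residue - 2]
            hw = max(p.phi_halfwidth, p.psi_halfwidth) + extra
            diff = (theta - center + 180.0) % 360.0 - 180.0
            viol = math.radians(max(0.0, abs(diff) - hw))
            brute.append(0.5 * 15.0 * viol**2)
        expected = sum(sorted(brute)[: math.ceil(0.7 * len(brute))])
        assert torsion_energy(conf, t) == pytest.approx(expected)


class TestLikelihoodEnergy:
    def test_zero_scale_enforces_nothing(self, rng):
        conf = _conf(rng.normal(0, 5, (10, 3)))
        coll = _random_collection(rng, 10, 5, 3, 0.8)
        assert likelihood_energy(conf, coll, None, scale=0.0) == 0.0

    def test_linear_in_scale_within_quadratic_regime(self, rng):
        conf = _conf(rng.normal(0, 3, (10, 3)))
        coll = _random_collection(rng, 10, 6, 3, 0.8)
        e_full = likelihood_energy(conf, coll, None, scale=1.0)
        e_half = likelihood_energy(conf, coll, None, scale=0.5)
        assert e_half == pytest.approx(0.5 * e_full)
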