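import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sparsemeld.cg_sampler import (
    KB,
    LadderSchedule,
    PriorParams,
    attempt_exchange,
    build_ladder,
    mc_sweep,
    prior_energy,
    run_remd,
)
from sparsemeld.conformation import (
    Conformation,
    bond_angles,
    bond_lengths,
    chain_from_internal,
    extended_chain,
    pseudo_dihedrals,
)
from sparsemeld.restraints import build_restraint_collection
from sparsemeld.io_formats import Interpretation, Peak


class TestBuildLadder:
    def test_protocol_ladder_contract(self):
        """30 replicas, 400–550 K: geometric rise to the plateau replica,
        constant above it; force scalar 1 at the plateau, 0 at the top."""
        lad = build_ladder(30, 400.0, 550.0, 12)
        assert lad.temperature[0] == pytest.approx(400.0)
        assert np.all(lad.temperature[12:] == pytest.approx(550.0))
        ratios = lad.temperature[1:13] / lad.temperature[:12]
        assert np.allclose(ratios, ratios[0])
        assert lad.alpha[12] == 1.0 and lad.alpha[29] == 0.0

    def test_equal_endpoints_give_flat_temperature(self):
        lad = build_ladder(8, 500.0, 500.0, 3)
        assert np.all(lad.temperature == 500.0)

    def test_monotonicity_invariants(self):
        lad = build_ladder(16, 300.0, 550.0, 7, alpha_exponent=2.0)
        assert np.all(np.diff(lad.temperature) >= -1e-12)
        assert np.all(np.diff(lad.alpha) <= 1e-12)
        assert np.all((lad.alpha == 1.0) == (np.arange(16) <= 7))

    def test_invalid_plateau_rejected(self):
        with pytest.raises(ValueError):
            build_ladder(6, 300.0, 550.0, 6)

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(
        n=st.integers(2, 40),
        t_min=st.floats(50.0, 500.0),
        spread=st.floats(0.0, 400.0),
        data=st.data(),
        q=st.floats(0.5, 4.0),
    )
    def test_schedule_invariants_hold_for_any_parameters(
        self, n, t_min, spread, data, q
    ):
        plateau = data.draw(st.integers(0, n - 1))
        lad = build_ladder(n, t_min, t_min + spread, plateau, q)
        assert lad.temperature[0] == pytest.approx(t_min if plateau > 0 else t_min + spread)
        assert np.all(np.diff(lad.temperature) >= -1e-9)
        assert np.all(np.diff(lad.alpha) <= 1e-12)
        assert np.all((lad.alpha == 1.0) == (np.arange(n) <= plateau))
        assert lad.alpha[-1] == (0.0 if plateau < n - 1 else 1.0)


def _ideal_chain(n, angle=120.0, dihedral=60.0):
    return Conformation(
        chain_from_internal(
            np.full(n - 1, 3.8), np.full(n - 2, angle), np.full(n - 3, dihedral)
        )
    )


class TestPriorEnergy:
    def test_ideal_chain_has_zero_energy(self):
        p = PriorParams()
        conf = _ideal_chain(10, angle=p.angle_center, dihedral=60.0)
        assert prior_energy(conf, p) == pytest.approx(0.0, abs=1e-9)

    def test_clash_is_penalised(self):
        p = PriorParams()
        coords = np.array([[0, 0, 0], [3.8, 0, 0], [1.0, 1.0, 0.0]])
        assert prior_energy(Conformation(coords), p) > 0.0

    def test_term_by_term_hand_evaluation(self, rng):
        """Each prior term matches an independent recomputation."""
        p = PriorParams(ss_bias=[(4, 50.0, 20.0, 12.0), (6, 180.0, 30.0, 9.0)])
        coords = rng.normal(0, 4, (12, 3))
        b = bond_lengths(coords)
        e_bond = 0.5 * p.k_bond * np.sum((b - p.bond_length) ** 2)
        ang = bond_angles(coords)
        lo = p.angle_center - p.angle_halfwidth
        e_ang = 0.5 * p.k_angle * np.sum(np.radians(np.maximum(0, lo - ang)) ** 2)
        e_rep = 0.0
        for i in range(12):
            for j in range(i + 2, 12):
                d = np.linalg.norm(coords[i] - coords[j])
                if d < p.excluded_radius:
                    e_rep += 0.5 * p.k_repulsion * (p.excluded_radius - d) ** 2
        dihs = pseudo_dihedrals(coords)
        e_chir = 0.5 * p.k_chirality * np.sum(
            np.maximum(0.0, -np.sin(np.radians(dihs))) ** 2
        )
        e_ss = 0.0
        for res, center, hw, k in p.ss_bias:
            diff = (dihs[res - 2] - center + 180.0) % 360.0 - 180.0
            e_ss += 0.5 * k * math.radians(max(0.0, abs(diff) - hw)) ** 2
        expected = e_bond + e_ang + e_rep + e_chir + e_ss
        assert prior_energy(coords, p) == pytest.approx(expected)

    def test_compiled_kernel_matches_reference(self, rng):
        """The jitted posterior equals the numpy reference path exactly."""
        from sparsemeld._kernels import PriorArrays, posterior_energy
        from sparsemeld.cg_sampler import _replica_energy_fn

        peaks = [
            Peak(
                f"p{i}",
                [
                    Interpretation(
                        int(rng.integers(1, 15)), "CA", int(rng.integers(1, 15)), "CA",
                        upper_bound=float(rng.uniform(3, 8)),
                    )
                    for _ in range(int(rng.integers(1, 4)))
                ],
            )
            for i in range(12)
        ]
        coll = build_restraint_collection(peaks, k=350.0, accuracy=0.7)
        prior = PriorParams(ss_bias=[(5, 50.0, 25.0, 15.0)])
        pa = PriorArrays(prior).as_tuple()
        c = coll.compiled()
        like = (c.idx_i, c.idx_j, c.d_low, c.d_high, c.k_a, c.onset,
                c.group_starts, c.n_active)
        for alpha in (0.0, 0.4, 1.0):
            ref_fn = _replica_energy_fn(coll, None, prior, alpha)
            for _ in range(20):
                x = rng.normal(0, 6, (14, 3))
                assert posterior_energy(x, alpha, *pa, *like) == pytest.approx(
                    ref_fn(x), rel=1e-12, abs=1e-12
                )


class TestMcSweep:
    def test_zero_energy_change_is_always_accepted(self, rng):
        conf = extended_chain(6)
        out, e = mc_sweep(conf, lambda c: 0.0, 300.0, rng)
        assert e == 0.0  # flat landscape: every proposal accepted

    def test_low_temperature_limit_is_downhill(self, rng):
        p = PriorParams()
        conf = Conformation(extended_chain(8).coords + rng.normal(0, 0.4, (8, 3)))
        energies = [prior_energy(conf.coords, p)]
        state = conf
        for _ in range(40):
            state, e = mc_sweep(state, lambda c: prior_energy(c, p), 1e-9, rng)
            energies.append(e)
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))

    def test_free_chain_bond_distribution_matches_boltzmann(self, rng):
        """With only the harmonic bond term, bond lengths are Gaussian with
        variance kT/k; the sampled std must agree within 3σ."""
        p = PriorParams(k_angle=0.0, k_repulsion=0.0, k_chirality=0.0)
        t = 300.0
        state = extended_chain(5)
        samples = []
        for sweep in range(3000):
            state, _ = mc_sweep(state, lambda c: prior_energy(c, p), t, rng)
            if sweep >= 500 and sweep % 5 == 0:
                samples.extend(bond_lengths(state.coords))
        samples = np.asarray(samples)
        sigma_expected = math.sqrt(KB * t / p.k_bond)
        n_eff = 400  # generous lower bound given autocorrelation
        tol = 3 * sigma_expected / math.sqrt(2 * n_eff)
        assert samples.std() == pytest.approx(sigma_expected, abs=tol)
        assert samples.mean() == pytest.approx(p.bond_length, abs=0.05)


class TestAttemptExchange:
    def _ladder(self, temps, alphas):
        return LadderSchedule(len(temps), np.array(temps), np.array(alphas), 0)

    def test_identical_configurations_always_swap(self, rng):
        lad = self._ladder([300.0, 400.0], [1.0, 0.5])
        conf = extended_chain(6)
        states = [conf.copy(), conf.copy()]
        energies = [lambda c: prior_energy(c, PriorParams())] * 2
        assert attempt_exchange(0, 1, states, lad, energies, rng)

    def test_identical_parameters_always_swap(self, rng):
        lad = self._ladder([350.0, 350.0], [0.7, 0.7])
        states = [
            Conformation(rng.normal(0, 4, (6, 3))),
            Conformation(rng.normal(0, 4, (6, 3))),
        ]
        e = lambda c: prior_energy(c, PriorParams())
        assert attempt_exchange(0, 1, states, lad, [e, e], rng)

    def test_acceptance_matches_hand_computed_delta(self, rng):
        lad = self._ladder([200.0, 500.0], [1.0, 0.0])
        xa = rng.normal(0, 4, (6, 3))
        xb = rng.normal(0, 4, (6, 3))
        e0 = lambda c: float((c**2).sum())
        e1 = lambda c: float(np.abs(c).sum())
        b0 = 1.0 / (KB * 200.0)
        b1 = 1.0 / (KB * 500.0)
        delta = b0 * (e0(xb) - e0(xa)) + b1 * (e1(xa) - e1(xb))
        p_accept = min(1.0, math.exp(-delta)) if delta > 0 else 1.0
        accepted = 0
        trials = 400
        for _ in range(trials):
            states = [Conformation(xa.copy()), Conformation(xb.copy())]
            accepted += attempt_exchange(0, 1, states, lad, [e0, e1], rng)
        se = math.sqrt(max(p_accept * (1 - p_accept), 1e-6) / trials)
        assert accepted / trials == pytest.approx(p_accept, abs=max(4 * se, 0.02))

    def test_non_neighbour_exchange_rejected(self, rng):
        lad = self._ladder([300.0, 400.0, 500.0], [1.0, 0.5, 0.0])
        with pytest.raises(ValueError):
            attempt_exchange(0, 2, [None, None, None], lad, [], rng)


class TestRunRemd:
    def _tiny_collection(self):
        peaks = [
            Peak("p1", [Interpretation(1, "CA", 5, "CA", upper_bound=7.0)]),
            Peak("p2", [Interpretation(2, "CA", 8, "CA", upper_bound=7.0)]),
        ]
        return build_restraint_collection(peaks, k=350.0, accuracy=1.0)

    def test_identical_seeds_give_byte_identical_results(self):
        lad = build_ladder(3, 200.0, 400.0, 1, 1.0)
        coll = self._tiny_collection()
        kw = dict(n_sweeps=40, exchange_stride=5, save_stride=10, seed=7)
        r1 = run_remd(extended_chain(8), coll, None, lad, **kw)
        r2 = run_remd(extended_chain(8), coll, None, lad, **kw)
        for f1, f2 in zip(r1.frames, r2.frames):
            assert np.array_equal(f1, f2)
        assert np.array_equal(r1.exchange_acceptance, r2.exchange_acceptance)

    def test_single_replica_is_plain_mc(self):
        lad = build_ladder(2, 300.0, 300.0, 1, 1.0)
        lad_single = LadderSchedule(1, np.array([300.0]), np.array([1.0]), 0)
        run = run_remd(
            extended_chain(8), self._tiny_collection(), None, lad_single,
            n_sweeps=30, save_stride=10, seed=0,
        )
        assert run.n_replicas == 1
        assert len(run.frames[0]) == 3

    def test_equal_frame_counts_and_selection_log(self):
        lad = build_ladder(3, 250.0, 450.0, 1, 1.0)
        run = run_remd(
            extended_chain(10), self._tiny_collection(), None, lad,
            n_sweeps=60, save_stride=20, seed=1,
        )
        assert all(len(f) == 3 for f in run.frames)
        assert all(len(s) == 3 for s in run.selection_log)
        assert np.all((run.exchange_acceptance >= 0) & (run.exchange_acceptance <= 1))

    def test_alpha_zero_samples_the_prior(self):
        """With no restraint weight anywhere and one temperature, bond-length
        moments match the closed-form harmonic result."""
        t = 300.0
        lad = LadderSchedule(2, np.array([t, t]), np.array([0.0, 0.0]), 0)
        prior = PriorParams(k_angle=0.0, k_repulsion=0.0, k_chirality=0.0)
        run = run_remd(
            extended_chain(5), None, None, lad,
            prior=prior, n_sweeps=2500, exchange_stride=10, save_stride=5, seed=3,
        )
        bonds = np.concatenate(
            [bond_lengths(f) for f in run.frames[0][100:]]
        )
        sigma = math.sqrt(KB * t / prior.k_bond)
        assert bonds.mean() == pytest.approx(prior.bond_length, abs=0.05)
        assert bonds.std() == pytest.approx(sigma, abs=0.35 * sigma)

    def test_exchange_between_identical_replicas_is_certain(self):
        t = 350.0
        lad = LadderSchedule(2, np.array([t, t]), np.array([1.0, 1.0]), 1)
        run = run_remd(
            extended_chain(8), self._tiny_collection(), None, lad,
            n_sweeps=50, exchange_stride=5, save_stride=25, seed=2,
        )
        assert run.exchange_acceptance[0] == 1.0
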