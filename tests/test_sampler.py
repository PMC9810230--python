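"""Monte Carlo move set, acceptance rules, and sampler statistical checks."""

import numpy as np
import pytest
from scipy import stats

from polyphase import ModelParams, total_energy
from polyphase.model import Conformation
from polyphase.sampler import (
    RunConfig,
    TemperatureLadder,
    adapt_step_size,
    displacement_move,
    metropolis_accept,
    pivot_move,
    replica_swap,
    reptation_move,
    run_remc,
    sample_chain,
    simulated_annealing,
    straight_chain,
)

from conftest import random_valid_conformation


class TestAcceptanceRules:
    def test_metropolis_downhill_and_ties_always_accepted(self):
        assert metropolis_accept(0.0, -1.0, 0.5, 0.999999)
        assert metropolis_accept(1.0, 1.0, 0.5, 0.999999)

    def test_metropolis_half_probability_point(self):
        # dE = T ln 2 makes the acceptance probability exactly 1/2
        t = 0.7
        de = t * np.log(2.0)
        assert metropolis_accept(0.0, de, t, 0.4999)
        assert not metropolis_accept(0.0, de, t, 0.5001)

    def test_metropolis_rejects_infinite_proposals(self):
        assert not metropolis_accept(0.0, np.inf, 1.0, 0.0)

    def test_swap_certain_for_equal_energies(self):
        assert replica_swap(-3.0, -3.0, 0.5, 0.7, 0.999999)

    def test_swap_half_probability_point(self):
        # choose energies so the exponent equals -ln 2
        t_k, t_k1 = 0.5, 1.0
        de = np.log(2.0) / (1 / t_k - 1 / t_k1)  # E_k - E_k1 = -de
        assert replica_swap(0.0, de, t_k, t_k1, 0.4999)
        assert not replica_swap(0.0, de, t_k, t_k1, 0.5001)


class TestTemperatureLadder:
    def test_geometric_ladder_spans_interval(self):
        lad = TemperatureLadder.geometric(0.1, 5.0, 10)
        assert lad.count == 10
        assert lad.temperatures[0] == pytest.approx(0.1)
        assert lad.temperatures[-1] == pytest.approx(5.0)
        ratios = lad.temperatures[1:] / lad.temperatures[:-1]
        assert np.allclose(ratios, ratios[0])

    def test_rejects_unsorted_or_nonpositive(self):
        with pytest.raises(ValueError):
            TemperatureLadder(np.array([1.0, 0.5]))
        with pytest.raises(ValueError):
            TemperatureLadder(np.array([-0.1, 0.5]))


class TestMoves:
    def test_displacement_moves_exactly_one_monomer(self, rng, params):
        conf = random_valid_conformation(10, rng, params)
        before = conf.positions.copy()
        prop = displacement_move(conf, 4, 0.3, rng)
        changed = np.any(prop.positions != before, axis=1)
        assert changed[4] and changed.sum() == 1
        assert np.all(prop.positions[changed == False] == before[changed == False])  # noqa: E712

    def test_zero_box_is_identity(self, rng, params):
        conf = random_valid_conformation(5, rng, params)
        prop = displacement_move(conf, 2, 0.0, rng)
        assert np.array_equal(prop.positions, conf.positions)

    def test_displacement_components_uniform(self, params):
        rng = np.random.default_rng(77)
        conf = straight_chain(3)
        r_d = 0.8
        shifts = np.array(
            [displacement_move(conf, 1, r_d, rng).positions[1] - conf.positions[1]
             for _ in range(3000)]
        )
        for axis in range(3):
            u = (shifts[:, axis] + r_d / 2) / r_d
            assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_displacement_flags_broken_bond(self, params):
        rng = np.random.default_rng(5)
        conf = straight_chain(3)
        # huge box: most proposals break a FENE bond and must come back flagged
        flagged = sum(
            displacement_move(conf, 1, 20.0, rng, params).auto_reject for _ in range(200)
        )
        assert flagged > 150

    def test_pivot_is_rigid_on_tail(self, rng, params):
        conf = random_valid_conformation(12, rng, params)
        i = 4
        prop = pivot_move(conf, i, rng)
        # head untouched
        assert np.array_equal(prop.positions[: i + 1], conf.positions[: i + 1])
        # pivot bond length and all tail-internal distances preserved
        old, new = conf.positions, prop.positions
        assert np.linalg.norm(new[i + 1] - new[i]) == pytest.approx(
            np.linalg.norm(old[i + 1] - old[i]), abs=1e-12
        )
        tail_old = old[i + 1:] - old[i + 1]
        tail_new = new[i + 1:] - new[i + 1]
        d_old = np.linalg.norm(tail_old[:, None] - tail_old[None, :], axis=-1)
        d_new = np.linalg.norm(tail_new[:, None] - tail_new[None, :], axis=-1)
        assert np.allclose(d_old, d_new, atol=1e-12)

    def test_reptation_shifts_indices(self, rng, params):
        conf = random_valid_conformation(8, rng, params)
        prop = reptation_move(conf, rng)
        old, new = conf.positions, prop.positions
        # either head->tail or tail->head: interior coordinates are reused
        head = np.array_equal(new[:-1], old[1:])
        tail = np.array_equal(new[1:], old[:-1])
        assert head or tail

    def test_adaptive_feedback_is_monotone(self):
        assert adapt_step_size(0.8, 1.0) > 1.0
        assert adapt_step_size(0.2, 1.0) < 1.0
        assert adapt_step_size(0.5, 1.0) == pytest.approx(1.0)


class TestSampleChain:
    def test_same_seed_is_bit_identical(self, params):
        a = sample_chain(params, 5, 1.0, sweeps=200, seed=42, tuning_blocks=5,
                         equilibration=50)
        b = sample_chain(params, 5, 1.0, sweeps=200, seed=42, tuning_blocks=5,
                         equilibration=50)
        assert np.array_equal(a.energies, b.energies)
        assert a.r_d == b.r_d

    def test_tuning_reaches_target_acceptance(self, params):
        r = sample_chain(params, 13, 1.0, sweeps=2000, seed=3)
        assert 0.45 <= r.acceptance <= 0.55

    def test_dimer_bond_distribution_matches_quadrature(self, params):
        """Detailed balance: stationary p(r) ~ r^2 exp(-V_B(r)/T)."""
        from polyphase.model import bond_potential
        from scipy.integrate import quad

        t = 0.5
        run = sample_chain(
            params, 2, t, sweeps=120_000, seed=9, measure_every=10, pivot_interval=0,
            observable=lambda pos: float(np.linalg.norm(pos[1] - pos[0])),
        )
        lo, hi = 1 - 3 / 7 + 1e-6, 1 + 3 / 7 - 1e-6
        xs = np.linspace(lo, hi, 2001)
        pdf = xs**2 * np.exp(-np.asarray(bond_potential(xs, params)) / t)
        cdf = np.concatenate([[0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(xs))])
        cdf /= cdf[-1]
        edges = np.interp(np.linspace(0, 1, 21), cdf, xs)
        edges[0], edges[-1] = lo - 1e-9, hi + 1e-9
        obs = np.histogram(run.observables, bins=edges)[0]
        assert stats.chisquare(obs).pvalue > 0.01


class TestRunRemc:
    @pytest.fixture(scope="class")
    def tiny_run(self, params):
        cfg = RunConfig(
            n_monomers=3, ladder=TemperatureLadder(np.array([0.8, 1.5])),
            sweeps=400, equilibration=100, tuning_blocks=10, tuning_block_sweeps=20,
            exchange_period=50, bin_width=0.2, seed=11,
        )
        return cfg, run_remc(cfg, params)

    def test_histogram_bookkeeping(self, tiny_run):
        cfg, hists = tiny_run
        assert hists.counts.shape[0] == 2
        assert np.all(hists.counts.sum(axis=1) == hists.m_k)
        assert np.all(hists.m_k == cfg.sweeps)
        assert np.isfinite(hists.min_energy)
        assert hists.min_conformation is not None

    def test_same_seed_bit_identical(self, tiny_run, params):
        cfg, hists = tiny_run
        again = run_remc(cfg, params)
        assert np.array_equal(hists.counts, again.counts)
        assert np.array_equal(hists.bin_edges, again.bin_edges)
        assert hists.min_energy == again.min_energy
        assert np.array_equal(hists.min_conformation, again.min_conformation)

    def test_exchange_preserves_canonical_marginals(self, params):
        """Per-thread mean energies agree with and without replica swaps."""
        def mean_se(exchange_period):
            cfg = RunConfig(
                n_monomers=3, ladder=TemperatureLadder(np.array([0.8, 1.5])),
                sweeps=4000, equilibration=300, tuning_blocks=10,
                tuning_block_sweeps=20, exchange_period=exchange_period, seed=21,
            )
            h = run_remc(cfg, params)
            e = h.bin_centers
            means, ses = [], []
            for k in range(2):
                w = h.counts[k] / h.counts[k].sum()
                m = np.sum(w * e)
                var = np.sum(w * (e - m) ** 2)
                means.append(m)
                ses.append(np.sqrt(var / (h.m_k[k] / 20)))  # ~20-sweep correlation blocks
            return np.array(means), np.array(ses)

        m_swap, se_swap = mean_se(100)
        m_noswap, se_noswap = mean_se(10**9)
        comb = np.hypot(se_swap, se_noswap)
        assert np.all(np.abs(m_swap - m_noswap) < 3 * comb)

    def test_ergodicity_from_different_starts(self):
        """Straight-chain and random-coil starts give consistent mean energy."""
        p = ModelParams(kappa=1.0)
        from polyphase.sampler import _random_coil

        results = []
        for init in (straight_chain(13), _random_coil(13, np.random.default_rng(1))):
            r = sample_chain(p, 13, 1.5, sweeps=4000, seed=17, equilibration=1000,
                             initial=init)
            block = r.energies[: 4000 // 40 * 40].reshape(-1, 40).mean(axis=1)
            results.append((r.energies.mean(), block.std(ddof=1) / np.sqrt(block.size)))
        (m1, s1), (m2, s2) = results
        assert abs(m1 - m2) < 3 * np.hypot(s1, s2)


class TestSimulatedAnnealing:
    def test_dimer_relaxes_to_bond_minimum(self, params):
        from polyphase.model import bond_potential

        best = simulated_annealing(
            params, 2, schedule=np.geomspace(1.0, 0.01, 10),
            sweeps_per_temperature=50, restarts=1, seed=0, refine_steps=3,
        )
        assert best.energy_cache == pytest.approx(float(bond_potential(1.0, params)), abs=1e-6)
        assert np.linalg.norm(best.positions[1] - best.positions[0]) == pytest.approx(1.0, abs=1e-4)

    def test_never_worse_than_initial_state(self, params, rng):
        initial = random_valid_conformation(6, rng, params)
        e0 = total_energy(initial, params).total
        best = simulated_annealing(
            params, 6, schedule=np.geomspace(1.0, 0.05, 5), sweeps_per_temperature=20,
            restarts=1, seed=1, initial=initial, refine_steps=3,
        )
        assert best.energy_cache <= e0 + 1e-12

    def test_schedule_must_decrease(self, params):
        with pytest.raises(ValueError):
            simulated_annealing(params, 3, schedule=np.array([0.5, 1.0]))
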