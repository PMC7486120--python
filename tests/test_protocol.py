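import numpy as np
import pytest

from ecosim import (
    BottleneckConfig,
    Environment,
    ProtocolError,
    StrategySet,
    ValidationError,
    bolus_schedule,
    bottleneck_sample,
    dilute,
    make_equally_spaced_strategies,
    run_batch,
    run_stochastic,
    run_to_steady_state,
)


class TestDilute:
    def test_proportional_renormalization(self):
        batch = _fake_batch(rho_final=np.array([0.6, 0.4]))
        np.testing.assert_allclose(dilute(batch, 1e-3), [6e-4, 4e-4], rtol=1e-15)

    def test_single_species(self):
        batch = _fake_batch(rho_final=np.array([0.123]))
        np.testing.assert_allclose(dilute(batch, 1e-3), [1e-3])

    def test_zero_biomass_rejected(self):
        batch = _fake_batch(rho_final=np.array([0.0, 0.0]))
        with pytest.raises(ValidationError):
            dilute(batch, 1e-3)


def _fake_batch(rho_final):
    from ecosim.batch import BatchResult

    env = Environment(c0=1.0, supply_fraction=[1.0], K=1.0, rho0=1e-3)
    return BatchResult(rho_init=rho_final * 0, rho_final=rho_final,
                       c_final=np.zeros(1), t_f=1.0, I=np.zeros(1),
                       consumed=np.zeros(1), produced=np.zeros(1),
                       terminated_by="depletion", env=env)


class TestDeterministicSteadyState:
    def test_single_species_trivially_steady(self):
        env = Environment(c0=1.0, supply_fraction=[0.5, 0.5], K=1.0, rho0=1e-3)
        res = run_to_steady_state([1e-3], StrategySet(alpha=[[0.5, 0.5]]), env)
        assert res.converged and res.batches_used == 1
        np.testing.assert_allclose(res.rho_star, [1e-3])

    def test_balanced_supply_keeps_equal_community(self, community21,
                                                   equal_inoculum21, env_balanced):
        """With a (0.5,0.5) bolus, the equal community is already at steady
        state and retains maximal diversity."""
        res = run_to_steady_state(equal_inoculum21, community21, env_balanced)
        assert res.converged
        np.testing.assert_allclose(res.rho_star, np.full(21, 1e-3 / 21), rtol=1e-9)
        assert res.diversity().m_e == pytest.approx(21.0, abs=1e-9)
        assert res.n_survivors == 21

    def test_steady_state_scaling_relation(self):
        """At steady state every species grows by (rho0+c0)/rho0 in a batch,
        so dilution reproduces the inoculum."""
        strategies = StrategySet(alpha=[[0.3, 0.7], [0.6, 0.4]])
        env = Environment(c0=1.0, supply_fraction=[0.45, 0.55], K=1.0, rho0=1e-3)
        res = run_to_steady_state([5e-4, 5e-4], strategies, env,
                                  steady_state_tol=1e-10, max_batches=2000)
        assert res.converged
        target_fold = (1e-3 + 1.0) / 1e-3
        np.testing.assert_allclose(res.final_batch.fold, target_fold, rtol=1e-6)
        np.testing.assert_allclose(dilute(res.final_batch, env.rho0), res.rho_star,
                                   rtol=1e-6)
        assert res.convergence_rate < 1.0
        assert res.rho_star.sum() == pytest.approx(1e-3, rel=1e-12)

    def test_supply_outside_hull_leaves_one_survivor(self):
        """Chemostat limit, two-nutrient supply outside the strategies'
        convex hull: competitive exclusion."""
        strategies = StrategySet(
            alpha=np.column_stack([np.linspace(0.3, 0.7, 5),
                                   1 - np.linspace(0.3, 0.7, 5)]))
        env = Environment(c0=1e-4, supply_fraction=[0.85, 0.15], K=1.0, rho0=1e-3)
        res = run_to_steady_state(np.full(5, 0.2), strategies, env,
                                  steady_state_tol=1e-8, max_batches=400)
        assert res.n_survivors == 1
        assert bool(res.survivors[-1])  # the strategy nearest the supply

    def test_survivors_stable_under_halved_tolerance(self):
        strategies = StrategySet(alpha=[[0.3, 0.7], [0.6, 0.4]])
        env = Environment(c0=1.0, supply_fraction=[0.25, 0.75], K=1.0, rho0=1e-3)
        res1 = run_to_steady_state([5e-4, 5e-4], strategies, env,
                                   steady_state_tol=1e-8, max_batches=2000)
        res2 = run_to_steady_state([5e-4, 5e-4], strategies, env,
                                   steady_state_tol=5e-9, max_batches=2000)
        np.testing.assert_array_equal(res1.survivors, res2.survivors)
        assert res1.n_survivors == 1


class TestBottleneckSampling:
    def make_batch(self, rho_final):
        return _two_species_batch(rho_final)

    def test_cell_bookkeeping(self):
        """1008-cell bottleneck with a 50-cell spike-in: 958 resident cells
        drawn, totals exact."""
        batch = _two_species_batch(np.array([0.6, 0.4]))
        config = BottleneckConfig(n_cells=1008, n_spikein=50,
                                  pool_fractions=np.array([0.5, 0.5]))
        rng = np.random.default_rng(0)
        counts = bottleneck_sample(batch, config, batch.env, rng)
        assert counts.sum() == 1008
        resident_only = bottleneck_sample(
            batch, BottleneckConfig(n_cells=958), batch.env,
            np.random.default_rng(0))
        assert resident_only.sum() == 958

    def test_single_species_zero_variance(self):
        batch = _two_species_batch(np.array([1.0, 0.0]))
        config = BottleneckConfig(n_cells=100)
        for seed in range(5):
            counts = bottleneck_sample(batch, config, batch.env,
                                       np.random.default_rng(seed))
            np.testing.assert_array_equal(counts, [100, 0])

    def test_population_too_small(self):
        batch = _two_species_batch(np.array([1e-6, 1e-6]))
        config = BottleneckConfig(n_cells=10**6)
        with pytest.raises(ProtocolError):
            bottleneck_sample(batch, config, batch.env, np.random.default_rng(0))

    def test_sampling_is_unbiased(self):
        """Mean sampled fractions match the final biomass fractions
        (hypergeometric sampling is unbiased)."""
        batch = _two_species_batch(np.array([0.731, 0.269]))
        config = BottleneckConfig(n_cells=1008)
        rng = np.random.default_rng(12)
        n_rep = 2000
        fracs = np.empty((n_rep, 2))
        for r in range(n_rep):
            fracs[r] = bottleneck_sample(batch, config, batch.env, rng) / 1008
        se = fracs.std(axis=0, ddof=1) / np.sqrt(n_rep)
        true = batch.rho_final / batch.rho_final.sum()
        assert np.all(np.abs(fracs.mean(axis=0) - true) < 3 * se + 1e-12)

    def test_spikein_bounds_validated(self):
        with pytest.raises(ValidationError):
            BottleneckConfig(n_cells=10, n_spikein=11,
                             pool_fractions=np.array([1.0]))


def _two_species_batch(rho_final):
    from ecosim.batch import BatchResult

    env = Environment(c0=1.0, supply_fraction=[0.5, 0.5], K=1.0, rho0=1e-3)
    return BatchResult(rho_init=np.full(2, 5e-4), rho_final=rho_final,
                       c_final=np.zeros(2), t_f=1.0, I=np.zeros(2),
                       consumed=np.zeros(2), produced=np.zeros(2),
                       terminated_by="depletion", env=env)


class TestStochasticProtocol:
    def test_pure_migration_reproduces_pool(self):
        """When every cell is a spike-in, the average composition is the
        pool composition."""
        strategies = make_equally_spaced_strategies(3)
        env = Environment(c0=1.0, supply_fraction=[0.5, 0.5], K=1.0, rho0=1e-3)
        pool = np.array([0.2, 0.5, 0.3])
        config = BottleneckConfig(n_cells=500, n_spikein=500, pool_fractions=pool)
        res = run_stochastic(np.full(3, 1 / 3), strategies, env, config,
                             n_batches=40, rng=np.random.default_rng(1))
        assert np.all(np.abs(res.mean_fractions - pool) < 0.06)

    def test_seeded_runs_are_bit_reproducible(self):
        strategies = make_equally_spaced_strategies(5)
        env = Environment(c0=1.0, supply_fraction=[0.5, 0.5], K=1.0, rho0=1e-3)
        config = BottleneckConfig(n_cells=200, n_spikein=10,
                                  pool_fractions=np.full(5, 0.2))
        runs = [run_stochastic(np.full(5, 0.2), strategies, env, config,
                               n_batches=10, rng=np.random.default_rng(7))
                for _ in range(2)]
        np.testing.assert_array_equal(runs[0].counts_history, runs[1].counts_history)


class TestBolusSchedule:
    def test_mixed_is_constant(self):
        env = Environment(c0=1.0, supply_fraction=[0.5, 0.5], K=1.0)
        np.testing.assert_array_equal(bolus_schedule(env, "mixed"), [[0.5, 0.5]])

    def test_alternating_equal_cycle(self):
        env = Environment(c0=1.0, supply_fraction=[0.5, 0.5], K=1.0)
        np.testing.assert_array_equal(bolus_schedule(env, "alternating", 2),
                                      [[1, 0], [0, 1]])

    def test_unrepresentable_cycle_rejected(self):
        env = Environment(c0=1.0, supply_fraction=[1 / 3, 2 / 3], K=1.0)
        with pytest.raises(ValidationError):
            bolus_schedule(env, "alternating", 2)

    def test_alternating_boluses_lower_diversity(self, community21,
                                                 equal_inoculum21, env_balanced):
        """Cycles of pure single-nutrient boluses support less diversity
        than the equivalent mixed bolus."""
        mixed = run_to_steady_state(equal_inoculum21, community21, env_balanced)
        sched = bolus_schedule(env_balanced, "alternating", 2)
        alt = run_to_steady_state(equal_inoculum21, community21, env_balanced,
                                  schedule=sched, steady_state_tol=1e-8,
                                  max_batches=600)
        assert alt.diversity().m_e < mixed.diversity().m_e - 1.0
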