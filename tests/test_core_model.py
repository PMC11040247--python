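"""Unit tests for the interaction operators and the simulation driver."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from noisybc import (ModelConfig, NoiseSpec, accept_selectivity,
                     adaptation_shift, apply_exogenous_jumps, bc_pair_update,
                     draw_ambiguous_message, run_simulation, simulation_step)

unit = st.floats(0.0, 1.0, allow_nan=False)


class TestPairUpdate:
    @pytest.mark.parametrize("x_i,m_j,eps,mu,expected", [
        (0.5, 0.6, 0.2, 0.5, 0.55),   # gap 0.1 within bound
        (0.1, 0.9, 0.2, 0.5, 0.1),    # gap 0.8 rejected
        (0.3, 0.5, 0.2, 0.5, 0.4),    # boundary gap accepted (non-strict)
    ])
    def test_examples(self, x_i, m_j, eps, mu, expected):
        assert bc_pair_update(x_i, m_j, eps, mu) == pytest.approx(expected)

    @given(x=unit, eps=unit, mu=st.floats(0.01, 0.5))
    def test_identical_opinions_are_fixed_points(self, x, eps, mu):
        assert bc_pair_update(x, x, eps, mu) == x

    @given(x=unit, m=unit, eps=unit, mu=st.floats(0.01, 0.5))
    def test_result_stays_in_unit_interval_and_moves_toward_message(
            self, x, m, eps, mu):
        out = bc_pair_update(x, m, eps, mu)
        assert 0.0 <= out <= 1.0
        assert abs(out - m) <= abs(x - m) + 1e-15

    def test_rejects_out_of_range_inputs(self):
        with pytest.raises(ValueError):
            bc_pair_update(1.5, 0.5, 0.2, 0.5)
        with pytest.raises(ValueError):
            bc_pair_update(0.5, -0.1, 0.2, 0.5)


class TestAmbiguousMessage:
    def test_zero_noise_returns_opinion_exactly(self, rng):
        assert draw_ambiguous_message(0.5, 0.0, rng) == 0.5

    def test_messages_always_in_unit_interval(self, rng):
        draws = np.array([draw_ambiguous_message(0.0, 0.05, rng)
                          for _ in range(20_000)])
        assert draws.min() >= 0.0 and draws.max() <= 1.0

    def test_boundary_sender_mean_matches_half_normal(self, rng):
        # sender at x=1 emits a half-normal message with mean 1 - nu*sqrt(2/pi)
        nu = 0.1
        draws = np.array([draw_ambiguous_message(1.0, nu, rng)
                          for _ in range(100_000)])
        expected = 1.0 - nu * math.sqrt(2.0 / math.pi)
        assert expected == pytest.approx(0.9202, abs=1e-4)
        se = draws.std() / math.sqrt(draws.size)
        assert draws.mean() == pytest.approx(expected, abs=4 * se)

    def test_interior_sender_matches_truncated_normal_density(self, rng):
        # acceptance probability of |m - x_i| <= eps under the truncated
        # normal message law, checked against scipy's truncnorm CDF
        x_j, x_i, eps, nu = 0.7, 0.5, 0.15, 0.1
        a, b = (0.0 - x_j) / nu, (1.0 - x_j) / nu
        law = stats.truncnorm(a, b, loc=x_j, scale=nu)
        p = law.cdf(x_i + eps) - law.cdf(x_i - eps)
        trials = 20_000
        hits = sum(abs(draw_ambiguous_message(x_j, nu, rng) - x_i) <= eps
                   for _ in range(trials))
        sd = math.sqrt(p * (1 - p) / trials)
        assert hits / trials == pytest.approx(p, abs=3 * sd)


class TestSelectivity:
    def test_boundary_gap_accepted_without_noise(self, rng):
        assert accept_selectivity(0.3, 0.5, 0.2, 0.0, rng)
        assert not accept_selectivity(0.3, 0.51, 0.2, 0.0, rng)

    @pytest.mark.parametrize("gap,eps,nu", [
        (0.3, 0.2, 0.1), (0.1, 0.2, 0.05), (0.25, 0.1, 0.2)])
    def test_acceptance_probability_matches_normal_tail(self, gap, eps, nu, rng):
        # P(accept) = P(xi >= gap - eps) = 1 - Phi((gap - eps)/nu)
        p = stats.norm.sf((gap - eps) / nu)
        trials = 20_000
        hits = sum(accept_selectivity(0.2, 0.2 + gap, eps, nu, rng)
                   for _ in range(trials))
        sd = math.sqrt(p * (1 - p) / trials)
        assert hits / trials == pytest.approx(p, abs=3.5 * sd)

    def test_zero_gap_accepted_at_least_half_the_time(self, rng):
        hits = sum(accept_selectivity(0.4, 0.4, 0.1, 0.3, rng)
                   for _ in range(5_000))
        assert hits / 5_000 >= 0.5 - 3 * math.sqrt(0.25 / 5_000)


class TestAdaptationShift:
    def test_zero_noise_is_identity(self, rng):
        assert adaptation_shift(0.55, 0.0, rng) == 0.55

    def test_interior_moments(self, rng):
        # truncation is negligible for an interior opinion
        draws = np.array([adaptation_shift(0.5, 0.1, rng)
                          for _ in range(100_000)])
        assert draws.mean() == pytest.approx(0.5, abs=0.002)
        assert draws.std() == pytest.approx(0.1, abs=0.002)

    def test_boundary_half_normal(self, rng):
        draws = np.array([adaptation_shift(1.0, 0.1, rng)
                          for _ in range(50_000)])
        assert draws.max() <= 1.0
        assert draws.mean() == pytest.approx(
            1.0 - 0.1 * math.sqrt(2 / math.pi), abs=0.002)


class TestExogenousJumps:
    def test_zero_noise_leaves_state_untouched(self, rng):
        x = rng.random(100)
        assert np.array_equal(apply_exogenous_jumps(x, 0.0, rng), x)

    def test_jump_count_matches_binomial(self, rng):
        n, sweeps, nu = 100, 10_000, 0.1
        x = np.full(n, 0.5)
        jumps = 0
        for _ in range(sweeps):
            y = apply_exogenous_jumps(x, nu, rng)
            jumps += int(np.count_nonzero(y != x))
        mean = n * sweeps * nu
        sd = math.sqrt(n * sweeps * nu * (1 - nu))
        assert abs(jumps - mean) <= 3 * sd

    def test_jump_amplitude_conditioned_on_jumping(self, rng):
        nu = 0.2
        x = np.full(2000, 0.5)
        deltas = []
        while len(deltas) < 20_000:
            y = apply_exogenous_jumps(x, nu, rng)
            moved = y != x
            deltas.extend((y[moved] - 0.5).tolist())
        sd = np.std(deltas)
        # slight contraction vs nu from truncation at +-0.5 (2.5 sigma)
        assert sd == pytest.approx(nu, abs=0.015)

    def test_probability_above_one_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_exogenous_jumps(np.full(10, 0.5), 1.5, rng)
        with pytest.raises(Exception):
            NoiseSpec(noise_type="exogenous", level=1.5)


class TestSimulationStep:
    def test_accepted_pair_converges_symmetrically(self, rng):
        cfg = ModelConfig(n=2, epsilon=0.3, mu=0.5, steps=1)
        out = simulation_step(np.array([0.2, 0.4]), cfg, rng)
        np.testing.assert_allclose(out, [0.3, 0.3])

    def test_pair_sum_conserved_without_noise(self, rng):
        cfg = ModelConfig(n=2, epsilon=1.0, mu=0.3, steps=1)
        x = np.array([0.213, 0.871])
        out = simulation_step(x, cfg, rng)
        assert out.sum() == pytest.approx(x.sum(), abs=1e-14)

    def test_rejects_wrong_state_size(self, rng):
        with pytest.raises(ValueError):
            simulation_step(np.array([0.1, 0.2]), ModelConfig(n=3), rng)


class TestRunSimulation:
    def test_same_seed_reproduces_bitwise(self):
        cfg = ModelConfig(steps=2_000, epsilon=0.2, seed=5,
                          noise=NoiseSpec(noise_type="ambiguity", level=0.1))
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        assert np.array_equal(a.snapshot_matrix, b.snapshot_matrix)
        assert a.summary.equals(b.summary)

    def test_first_and_final_snapshots_always_present(self):
        cfg = ModelConfig(steps=1_234, snapshot_every=500, seed=3)
        res = run_simulation(cfg)
        assert res.snapshot_steps[0] == 0
        assert res.snapshot_steps[-1] == 1_234
        assert set(res.snapshots) == {0, 500, 1000, 1234}

    def test_summary_recomputable_from_snapshots(self):
        from noisybc import summary_table
        cfg = ModelConfig(steps=3_000, seed=9,
                          noise=NoiseSpec(noise_type="exogenous", level=0.1))
        res = run_simulation(cfg)
        again = summary_table(res.snapshot_steps, res.snapshot_matrix)
        assert res.summary.equals(again)

    @pytest.mark.parametrize("noise_type", ["ambiguity", "selectivity",
                                            "adaptation", "exogenous"])
    def test_zero_noise_reproduces_noiseless_trajectory(self, noise_type):
        base = ModelConfig(steps=5_000, epsilon=0.25, seed=17)
        noiseless = run_simulation(base)
        noisy = run_simulation(base.model_copy(update={
            "noise": NoiseSpec(noise_type=noise_type, level=0.0)}))
        assert np.array_equal(noiseless.snapshot_matrix, noisy.snapshot_matrix)

    def test_small_world_topology_runs_and_respects_edges(self):
        cfg = ModelConfig(n=30, steps=2_000, topology="small_world",
                          sw_degree=4, sw_rewire=0.1, seed=2)
        res = run_simulation(cfg)
        assert res.final.min() >= 0.0 and res.final.max() <= 1.0
        assert res.interactions.sum() == 2 * cfg.steps


class TestRegimes:
    def test_uniform_state_is_fixed_point_many_to_one(self, rng):
        cfg = ModelConfig(n=10, regime="many_to_one", regime_k=3, steps=1)
        x = np.full(10, 0.42)
        np.testing.assert_array_equal(simulation_step(x, cfg, rng), x)

    def test_many_to_one_updates_one_agent_toward_sender_mean(self, rng):
        cfg = ModelConfig(n=3, regime="many_to_one", regime_k=2,
                          epsilon=1.0, mu=0.5, steps=1)
        x = np.array([0.1, 0.5, 0.9])
        out = simulation_step(x, cfg, rng)
        changed = np.flatnonzero(out != x)
        assert changed.size <= 1
        if changed.size == 1:
            i = changed[0]
            others = np.delete(x, i)
            assert out[i] == pytest.approx(x[i] + 0.5 * (others.mean() - x[i]))

    def test_one_to_many_broadcast_is_a_single_signal(self, rng):
        cfg = ModelConfig(n=5, regime="one_to_many", regime_k=3,
                          epsilon=1.0, mu=0.5, steps=1,
                          noise=NoiseSpec(noise_type="ambiguity", level=0.3))
        x = np.full(5, 0.5)
        out = simulation_step(x, cfg, rng)
        moved = np.unique(out[out != 0.5])
        # all three receivers saw the same noisy message
        assert moved.size == 1
        assert np.count_nonzero(out != 0.5) == 3

    def test_far_receivers_unchanged_one_to_many(self, rng):
        cfg = ModelConfig(n=5, regime="one_to_many", regime_k=3,
                          epsilon=0.01, mu=0.5, steps=1)
        x = np.array([0.0, 1.0, 1.0, 1.0, 1.0])
        out = simulation_step(x, cfg, rng)
        # any accepted update is between identical opinions -> no change
        np.testing.assert_array_equal(out, x)

    @pytest.mark.parametrize("regime", ["many_to_one", "one_to_many"])
    def test_zero_noise_equivalence_in_regimes(self, regime):
        base = ModelConfig(n=20, steps=3_000, regime=regime, regime_k=4,
                           epsilon=0.3, seed=23)
        noiseless = run_simulation(base)
        noisy = run_simulation(base.model_copy(update={
            "noise": NoiseSpec(noise_type="ambiguity", level=0.0)}))
        assert np.array_equal(noiseless.snapshot_matrix, noisy.snapshot_matrix)

    def test_fan_count_must_be_below_population(self):
        with pytest.raises(Exception):
            ModelConfig(n=5, regime="many_to_one", regime_k=5)
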