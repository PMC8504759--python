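"""Unit tests for the elementary model operations."""

import math

import numpy as np
import pytest

from idsim import ModelParams, SplitMix64, init_population, single_update
from idsim.model import (
    compute_utility,
    exploration_perturbation,
    local_neighbor_indices,
    migration_step,
    reinforcement_update,
    sample_global_partners,
    scale_strength,
    unscale_strength,
)
from idsim.reference import _brute_force_neighbor_sites

from conftest import make_state


class TestStrengthScaling:
    @pytest.mark.parametrize(
        "raw, expected",
        [(0.0, 0.0), (math.log(2), 0.5)],
    )
    def test_closed_form(self, raw, expected):
        assert scale_strength(raw) == pytest.approx(expected, abs=1e-15)

    def test_round_trip(self):
        assert scale_strength(unscale_strength(0.3)) == pytest.approx(0.3, abs=1e-15)

    def test_monotone(self):
        xs = np.linspace(0, 5, 50)
        ys = [scale_strength(x) for x in xs]
        assert all(b > a for a, b in zip(ys, ys[1:]))

    def test_negative_raw_rejected(self):
        with pytest.raises(ValueError):
            scale_strength(-0.1)


class TestLocalNeighbors:
    @pytest.mark.parametrize(
        "pos, n_loc, N, expected",
        [
            (0, 2, 200, [1, 199]),
            (0, 0, 200, []),
            (10, 5, 200, [8, 9, 11, 12, 13]),  # odd count: extra clockwise
            (0, 3, 200, [1, 2, 199]),
            (199, 2, 200, [0, 198]),
        ],
    )
    def test_examples(self, pos, n_loc, N, expected):
        assert local_neighbor_indices(pos, n_loc, N) == expected

    @pytest.mark.parametrize("pos", [0, 3, 11, 22])
    @pytest.mark.parametrize("n_loc", [1, 2, 5, 8])
    def test_matches_brute_force_ranking(self, pos, n_loc):
        N = 23
        assert local_neighbor_indices(pos, n_loc, N) == \
            _brute_force_neighbor_sites(pos, n_loc, N)

    def test_oversized_neighborhood_rejected(self):
        with pytest.raises(ValueError):
            local_neighbor_indices(0, 10, 10)


class TestGlobalPartners:
    def test_zero_requested_is_empty(self):
        state = make_state([0, 0, 0, 1, 1, 1])
        assert sample_global_partners(state, 0, 0, [], state.rng) == []

    def test_underfull_pool_returned_whole(self):
        state = make_state([0, 0, 0, 1, 1, 1])
        got = sample_global_partners(state, 0, 3, [], state.rng)
        assert sorted(got) == [1, 2]

    def test_partners_share_identity_and_respect_exclusion(self):
        state = make_state([0, 1, 0, 1, 0, 1, 0, 1])
        for _ in range(50):
            got = sample_global_partners(state, 1, 2, [3], state.rng)
            assert all(state.identities[j] == 1 for j in got)
            assert 3 not in got and 1 not in got
            assert len(got) == len(set(got)) == 2

    def test_uniform_selection_frequency(self):
        # pool of 5 same-identity candidates, one chosen per draw
        state = make_state([0] * 6)
        rng = state.rng
        counts = np.zeros(6)
        n = 10_000
        for _ in range(n):
            (j,) = sample_global_partners(state, 0, 1, [], rng)
            counts[j] += 1
        freqs = counts[1:] / n
        assert np.all(np.abs(freqs - 0.2) < 0.02)


class TestUtility:
    def test_mixed_partners(self):
        u = compute_utility(0.5, 0, [0.4, 0.6], [0, 1])
        assert u == pytest.approx(-0.10, abs=1e-12)

    def test_empty_partner_set(self):
        assert compute_utility(0.5, 0, [], []) == 0.0

    def test_saturated_in_group(self):
        u = compute_utility(0.95, 2, [0.95] * 8, [2] * 8)
        assert u == pytest.approx(8 * 0.9025, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_utility(0.5, 0, [0.4], [0, 1])

    def test_bounded_by_partner_count(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(1, 9)
            w = rng.uniform(0.05, 0.95, size=n)
            ks = rng.integers(0, 4, size=n)
            u = compute_utility(0.95, 0, w, ks)
            assert abs(u) <= n * 0.95**2 + 1e-12


class TestReinforcementUpdate:
    @pytest.mark.parametrize(
        "w, u, expected",
        [
            (0.5, 0.0, 0.5),                      # zero utility is a fixed point
            (0.05, 1.0, 0.05 + 0.5 * 1.0 * 0.95),  # = 0.525
            (0.9, 7.0, 0.95),                     # clamped at w_max
            (0.5, -10.0, 0.05),                   # clamped at w_min
        ],
    )
    def test_examples(self, w, u, expected):
        assert reinforcement_update(w, u, 0.5, 0.05, 0.95) == \
            pytest.approx(expected, abs=1e-12)

    def test_sign_of_change_follows_utility(self):
        for u in (-0.3, -0.01, 0.01, 0.3):
            out = reinforcement_update(0.5, u, 0.5, 0.05, 0.95)
            assert (out - 0.5) * u > 0


class TestExploration:
    def test_disabled_exploration_is_identity(self):
        rng = SplitMix64(1)
        for _ in range(100):
            assert exploration_perturbation(0.4, 0.0, 0.05, 0.05, 0.95, rng) == 0.4

    def test_perturbation_damped_near_upper_bound(self):
        rng = SplitMix64(2)
        for _ in range(1000):
            out = exploration_perturbation(0.95, 1.0, 0.05, 0.05, 0.95, rng)
            assert abs(out - 0.95) <= (1 - 0.95) * 0.05 + 1e-15

    def test_symmetric_mean_away_from_bounds(self):
        rng = SplitMix64(3)
        deltas = np.array([
            exploration_perturbation(0.5, 1.0, 0.05, 0.05, 0.95, rng) - 0.5
            for _ in range(10_000)
        ])
        sd = (1 - 0.5) * 0.05 / np.sqrt(3)  # sd of the uniform perturbation
        assert abs(deltas.mean()) < 3 * sd / np.sqrt(len(deltas))


class TestMigration:
    def test_zero_rate_moves_nobody(self):
        state = make_state([0, 1] * 10)
        before = state.pos_of_agent.copy()
        for _ in range(50):
            migration_step(state, 0.0, state.rng)
        assert np.array_equal(state.pos_of_agent, before)

    def test_positions_stay_a_permutation(self):
        state = make_state([0, 1, 2, 3] * 5)
        for _ in range(200):
            migration_step(state, 0.5, state.rng)
            assert np.array_equal(np.sort(state.pos_of_agent), np.arange(20))
            assert np.array_equal(
                state.agent_at_site[state.pos_of_agent], np.arange(20)
            )

    def test_one_expected_swap_moves_exactly_two_agents(self):
        # epsilon = 2/N gives exactly one pair swap per step
        N = 20
        state = make_state([0, 1] * 10)
        for _ in range(100):
            before = state.pos_of_agent.copy()
            migration_step(state, 2.0 / N, state.rng)
            assert np.sum(state.pos_of_agent != before) == 2

    def test_strengths_and_identities_travel_with_agents(self):
        state = make_state([0, 1, 2, 3] * 5, strengths=np.linspace(0.1, 0.9, 20))
        ids, ws = state.identities.copy(), state.strengths.copy()
        for _ in range(100):
            migration_step(state, 0.3, state.rng)
        assert np.array_equal(state.identities, ids)
        assert np.array_equal(state.strengths, ws)


class TestInitPopulation:
    def test_balanced_identity_counts(self, paper_params):
        state = init_population(paper_params)
        assert np.array_equal(np.bincount(state.identities), [50, 50, 50, 50])

    def test_all_strengths_start_at_lower_bound(self, paper_params):
        state = init_population(paper_params)
        assert np.all(state.strengths == 0.05)

    def test_remainder_goes_to_lowest_labels(self):
        state = init_population(ModelParams(N=10, M=3, n_loc=2, n_glob=1))
        assert np.array_equal(np.bincount(state.identities), [4, 3, 3])

    def test_seed_changes_placement_not_composition(self):
        a = init_population(ModelParams(seed=1))
        b = init_population(ModelParams(seed=2))
        assert np.array_equal(np.bincount(a.identities), np.bincount(b.identities))
        assert not np.array_equal(a.pos_of_agent, b.pos_of_agent)
        assert np.array_equal(np.sort(a.pos_of_agent), np.arange(200))


class TestSingleUpdate:
    def test_zero_dynamics_is_a_fixed_point(self):
        params = ModelParams(N=20, M=4, n_loc=3, n_glob=2,
                             d=0.0, p_expl=0.0, epsilon=0.0, seed=4)
        state = init_population(params)
        frozen = state.copy()
        for _ in range(500):
            single_update(state, params)
        assert np.array_equal(state.strengths, frozen.strengths)
        assert np.array_equal(state.pos_of_agent, frozen.pos_of_agent)

    def test_single_identity_never_loses_strength(self):
        # with no out-group every utility is >= 0
        params = ModelParams(N=16, M=1, n_loc=2, n_glob=2,
                             p_expl=0.0, seed=6)
        state = init_population(params)
        prev = state.strengths.copy()
        for _ in range(2000):
            single_update(state, params)
            assert np.all(state.strengths >= prev - 1e-15)
            prev = state.strengths.copy()

    def test_fixed_seed_reproduces_trajectory(self, small_params):
        a = init_population(small_params)
        b = init_population(small_params)
        for _ in range(500):
            single_update(a, small_params)
            single_update(b, small_params)
        assert np.array_equal(a.strengths, b.strengths)
        assert a.rng.state == b.rng.state
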