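"""Synthetic-data generator: topologies, trajectory statistics, noise."""

import numpy as np
import pytest

from timedhn.ctmc import HazardNetwork, Profile
from timedhn.simulate import (
    SimulationConfig,
    apply_noise,
    generate_dataset,
    noise_ladder,
    random_dag_network,
    random_forest_network,
    sample_profile,
    sample_trajectory,
)


def _config(n, topology="forest", **kw):
    return SimulationConfig(n=n, topology=topology, **kw)


class TestForestGenerator:
    def test_structure(self, rng):
        for _ in range(20):
            truth = random_forest_network(15, _config(15), rng)
            adj = truth.adjacency
            assert adj.sum() <= 14
            assert (adj.sum(axis=0) <= 1).all()  # in-degree at most one
            # spontaneous rates: 1 for roots, 0.1 otherwise
            diag = np.diag(truth.network.rates)
            roots = adj.sum(axis=0) == 0
            np.testing.assert_allclose(diag[roots], 1.0)
            np.testing.assert_allclose(diag[~roots], 0.1)
            # all inter-event weights are 1
            assert set(np.unique(truth.network.rates[adj.astype(bool)])) == {1.0}

    def test_max_depth_and_occupancy(self, rng):
        # n=15 -> depths 1..3; with every depth occupied the longest root
        # path has at most 2 edges
        import networkx as nx

        for _ in range(10):
            truth = random_forest_network(15, _config(15), rng)
            g = nx.from_numpy_array(truth.adjacency, create_using=nx.DiGraph)
            assert nx.dag_longest_path_length(g) <= 2

    def test_determinism(self):
        a = random_forest_network(10, _config(10), np.random.default_rng(5))
        b = random_forest_network(10, _config(10), np.random.default_rng(5))
        np.testing.assert_array_equal(a.adjacency, b.adjacency)

    def test_minimum_size(self, rng):
        with pytest.raises(ValueError):
            random_forest_network(1, _config(2), rng)


class TestDagGenerator:
    def test_edge_count_and_acyclicity(self, rng):
        import networkx as nx

        truth = random_dag_network(15, _config(15, "dag"), rng)
        assert truth.adjacency.sum() == 22  # floor(1.5 * 15)
        g = nx.from_numpy_array(truth.adjacency, create_using=nx.DiGraph)
        assert nx.is_directed_acyclic_graph(g)

    def test_infeasible_edge_count(self, rng):
        with pytest.raises(ValueError):
            random_dag_network(2, _config(2, "dag"), rng)

    def test_source_rates(self, rng):
        truth = random_dag_network(12, _config(12, "dag"), rng)
        diag = np.diag(truth.network.rates)
        sources = truth.adjacency.sum(axis=0) == 0
        np.testing.assert_allclose(diag[sources], 1.0)
        np.testing.assert_allclose(diag[~sources], 0.1)


class TestTrajectories:
    def test_monotone_one_bit_growth(self, rng):
        net = HazardNetwork(np.diag(np.full(6, 0.5)))
        times, states = sample_trajectory(net, 6, rng)
        assert (np.diff(times) > 0).all()
        for a, b in zip(states, states[1:]):
            assert (b >= a).all() and (b.sum() - a.sum()) == 1

    def test_sojourn_mean(self, rng):
        # single event, rate 2: mean first-jump time must be 1/2
        net = HazardNetwork([[2.0]])
        draws = np.array([sample_trajectory(net, 1, rng)[0][0] for _ in range(20000)])
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.5) < 3 * se

    def test_competing_exponentials_first_jump(self, rng):
        # chain a->b with R_aa=1, R_bb=0.1: P(first event = a) = 1/1.1
        R = np.array([[1.0, 10.0], [0.0, 0.1]])
        net = HazardNetwork(R)
        first_a = 0
        m = 20000
        for _ in range(m):
            _, states = sample_trajectory(net, 1, rng)
            first_a += states[1][0] == 1
        p = 1 / 1.1
        se = np.sqrt(p * (1 - p) / m)
        assert abs(first_a / m - p) < 4 * se

    def test_stuck_chain_raises(self, rng):
        net = HazardNetwork([[1.0, 0.0], [0.0, 0.0]])  # event 1 unreachable
        with pytest.raises(RuntimeError):
            sample_trajectory(net, 2, rng)


class TestSampleProfile:
    def test_cap_respected(self, rng):
        net = HazardNetwork(np.diag(np.full(12, 0.5)))
        for _ in range(50):
            profile, t = sample_profile(net, 10, rng)
            assert profile.k <= 10
            assert t >= 0

    def test_occupancy_matches_model(self, rng):
        """Empirical state at a fixed time matches e^{tQ} row 1."""
        from timedhn.ctmc import state_distribution

        R = np.array([[1.0, 2.0], [0.1, 0.3]])
        net = HazardNetwork(R)
        t_obs, m = 0.7, 30000
        counts = np.zeros(4)
        for _ in range(m):
            times, states = sample_trajectory(net, 2, rng)
            k = int(np.searchsorted(times, t_obs, side="right"))
            bits = states[k]
            counts[bits[0] + 2 * bits[1]] += 1
        model = state_distribution(net, t_obs)
        se = np.sqrt(model * (1 - model) / m)
        assert (np.abs(counts / m - model) < 4 * se + 1e-3).all()


class TestNoise:
    def test_identity_at_zero(self, rng):
        p = Profile([1, 0, 1])
        assert apply_noise(p, 0.0, rng) == p

    def test_flip_rate(self, rng):
        n, m, prob = 15, 10000, 0.05
        base = Profile(np.zeros(n, dtype=int))
        flips = sum(apply_noise(base, prob, rng).k for _ in range(m))
        mean = flips / m
        se = np.sqrt(n * prob * (1 - prob) / m)
        assert abs(mean - n * prob) < 3 * se

    def test_symmetric_flips(self, rng):
        ones = Profile(np.ones(20, dtype=int))
        noisy = apply_noise(ones, 0.5, rng)
        assert noisy.k < 20  # some 1 -> 0 flips occurred

    def test_ladder_is_nested(self, rng):
        levels = [0.001, 0.01, 0.05, 0.3]
        profiles = [Profile(row) for row in rng.integers(0, 2, (50, 10))]
        ladder = noise_ladder(profiles, levels, rng)
        for lo, hi in zip(levels, levels[1:]):
            for base, a, b in zip(profiles, ladder[lo], ladder[hi]):
                flipped_lo = base.bits != a.bits
                flipped_hi = base.bits != b.bits
                assert (flipped_lo <= flipped_hi).all()


class TestGenerateDataset:
    def test_shapes_and_cap(self):
        config = SimulationConfig(n=15, topology="forest", sample_size=100, seed=3)
        dataset, truth = generate_dataset(config)
        assert len(dataset) == 100
        assert all(p.k <= 10 for p in dataset.profiles)
        assert dataset.times.shape == (100,)
        assert truth.topology == "forest"

    def test_noise_stream_separated(self):
        clean, _ = generate_dataset(
            SimulationConfig(n=8, sample_size=50, seed=9, noise_prob=0.0)
        )
        noisy, _ = generate_dataset(
            SimulationConfig(n=8, sample_size=50, seed=9, noise_prob=0.05)
        )
        np.testing.assert_allclose(clean.times, noisy.times)
        # some but not all profiles altered
        diffs = sum(a != b for a, b in zip(clean.profiles, noisy.profiles))
        assert 0 < diffs < 50

    def test_distinct_networks_across_seeds(self):
        nets = set()
        for seed in range(20):
            _, truth = generate_dataset(
                SimulationConfig(n=10, sample_size=1, seed=seed)
            )
            nets.add(truth.adjacency.tobytes())
        assert len(nets) >= 19

    def test_reproducible(self):
        a, _ = generate_dataset(SimulationConfig(n=6, sample_size=30, seed=4))
        b, _ = generate_dataset(SimulationConfig(n=6, sample_size=30, seed=4))
        np.testing.assert_allclose(a.times, b.times)
        assert all(x == y for x, y in zip(a.profiles, b.profiles))

    def test_small_n_caps_max_events(self):
        config = SimulationConfig(n=6, sample_size=5, seed=0)
        assert config.max_events == 6
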