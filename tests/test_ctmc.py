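"""Core CTMC layer: indexing, generators, subspace restriction, likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.linalg import expm

from timedhn.ctmc import (
    ExpectedTimeUndefinedError,
    HazardNetwork,
    Profile,
    build_full_generator,
    build_subspace_generator,
    dec_index,
    expected_time,
    likelihood,
    state_distribution,
    subspace_index_map,
    transition_rate,
)

from conftest import random_network, random_profile


class TestTypes:
    def test_network_validation(self):
        with pytest.raises(ValueError):
            HazardNetwork([[1, 2], [3, -1]])
        with pytest.raises(ValueError):
            HazardNetwork([[1, np.inf], [0, 1]])
        with pytest.raises(ValueError):
            HazardNetwork(np.ones((2, 3)))
        net = HazardNetwork(np.eye(3), ["a", "b", "c"])
        assert net.n == 3 and net.event_names == ["a", "b", "c"]

    def test_profile_invariants(self):
        p = Profile([1, 0, 1, 0])
        assert p.k == 2 and p.active == (0, 2) and p.n == 4
        with pytest.raises(ValueError):
            Profile([0, 2])


class TestDecIndex:
    @pytest.mark.parametrize(
        "bits,expected",
        [
            ([0, 0, 0], 1),  # normal state
            ([1, 0, 0], 2),  # first basis entry: 2**0 + 1
            ([0, 1, 0], 3),
            ([1, 1], 4),  # full state maps to 2**n
        ],
    )
    def test_examples(self, bits, expected):
        assert dec_index(Profile(bits)) == expected

    @given(st.integers(1, 10), st.integers(0, 2**10 - 1))
    @settings(max_examples=50, deadline=None)
    def test_bijective(self, n, code):
        code %= 2**n
        bits = [(code >> i) & 1 for i in range(n)]
        assert dec_index(Profile(bits)) == code + 1


class TestTransitionRate:
    def test_examples(self):
        net = HazardNetwork([[1, 0.5], [0.2, 1]])
        assert transition_rate(net, Profile([0, 0]), 0) == 1.0
        assert transition_rate(net, Profile([1, 0]), 1) == pytest.approx(1.5)

    def test_irreversibility(self):
        net = HazardNetwork([[1, 0.5], [0.2, 1]])
        with pytest.raises(ValueError):
            transition_rate(net, Profile([1, 0]), 0)


class TestFullGenerator:
    def test_hand_evaluated_2x2(self):
        net = HazardNetwork([[1, 0.5], [0.2, 1]])
        Q = build_full_generator(net).Q
        # states ordered (00, 10, 01, 11)
        assert Q[0, 1] == 1.0 and Q[0, 2] == 1.0
        assert Q[1, 3] == pytest.approx(1.5)
        assert Q[2, 3] == pytest.approx(1.2)
        assert Q[3, 3] == 0.0
        np.testing.assert_allclose(Q.sum(axis=1), 0, atol=1e-12)

    def test_single_event_chain(self):
        Q = build_full_generator(HazardNetwork([[0.7]])).Q
        np.testing.assert_allclose(Q, [[-0.7, 0.7], [0.0, 0.0]])

    def test_upper_triangular_and_one_bit_structure(self, rng):
        net = random_network(rng, 5)
        Q = build_full_generator(net).Q
        assert np.allclose(np.tril(Q, -1), 0)
        for a in range(32):
            for b in range(32):
                if a != b and Q[a, b] != 0:
                    diff = a ^ b
                    assert diff & (diff - 1) == 0 and b > a  # one extra bit

    def test_cap(self):
        with pytest.raises(ValueError):
            build_full_generator(HazardNetwork(np.eye(13)))


class TestSubspace:
    def test_index_map_examples(self):
        np.testing.assert_array_equal(
            subspace_index_map(Profile([1, 0, 1])), [1, 2, 5, 6]
        )
        np.testing.assert_array_equal(subspace_index_map(Profile([0, 0])), [1])
        np.testing.assert_array_equal(
            subspace_index_map(Profile([1, 1])), [1, 2, 3, 4]
        )

    def test_endpoints(self, rng):
        for _ in range(10):
            p = random_profile(rng, 7)
            idx = subspace_index_map(p)
            assert idx[0] == 1 and idx[-1] == dec_index(p)
            assert len(idx) == 2**p.k

    def test_diagonal_counts_all_absent_events(self):
        net = HazardNetwork(np.eye(3))
        sub = build_subspace_generator(net, Profile([1, 0, 1]))
        np.testing.assert_allclose(np.diag(sub.generator), [-3, -2, -2, -1])

    def test_equals_full_restriction(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 9))
            net = random_network(rng, n)
            p = random_profile(rng, n)
            sub = build_subspace_generator(net, p)
            Q = build_full_generator(net).Q
            idx = sub.full_indices - 1
            np.testing.assert_allclose(sub.generator, Q[np.ix_(idx, idx)], atol=1e-12)

    def test_upper_triangular(self, rng):
        net = random_network(rng, 6)
        p = random_profile(rng, 6, k=4)
        assert np.allclose(np.tril(build_subspace_generator(net, p).generator, -1), 0)

    def test_k0_is_total_exit_rate(self):
        net = HazardNetwork([[0.3, 0], [0, 0.9]])
        sub = build_subspace_generator(net, Profile([0, 0]))
        np.testing.assert_allclose(sub.generator, [[-1.2]])

    def test_k_cap(self, rng):
        net = random_network(rng, 5)
        with pytest.raises(ValueError):
            build_subspace_generator(net, Profile([1] * 5), k_max=4)


class TestLikelihood:
    def test_single_event_closed_form(self):
        net = HazardNetwork([[1.0]])
        assert likelihood(net, Profile([1]), np.log(2)) == pytest.approx(0.5, abs=1e-12)
        for t in (0.1, 1.0, 3.0):
            assert likelihood(net, Profile([0]), t) == pytest.approx(
                np.exp(-t), abs=1e-12
            )

    def test_normal_state_survival(self, rng):
        net = random_network(rng, 5)
        t = 0.7
        expected = np.exp(-t * np.trace(net.rates))
        assert likelihood(net, Profile([0] * 5), t) == pytest.approx(expected, rel=1e-10)

    def test_matches_full_space(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 9))
            net = random_network(rng, n)
            p = random_profile(rng, n)
            t = float(rng.exponential(1.0))
            ref = expm(t * build_full_generator(net).Q)[0, dec_index(p) - 1]
            assert likelihood(net, p, t) == pytest.approx(ref, abs=1e-10)

    def test_gauge_invariance(self, rng):
        net = random_network(rng, 5)
        p = random_profile(rng, 5, k=3)
        base = likelihood(net, p, 1.3)
        for s in (0.5, 2.0, 10.0):
            assert likelihood(net.scaled(s), p, 1.3 / s) == pytest.approx(
                base, abs=1e-10
            )

    def test_chain_limit_hypoexponential(self):
        # pure chain 0 -> 1 -> 2: only the source has a real spontaneous rate
        eps = 1e-12
        R = np.array([[1.0, 2.0, 0.0], [0.0, eps, 3.0], [0.0, 0.0, eps]])
        net = HazardNetwork(R)
        t = 0.9
        # P(k=2 profile at t) = P(T1+T2 <= t < T1+T2+T3), rates 1, 2, 3
        rates = [1.0, 2.0, 3.0]

        def density_sum2(u):  # density of T1+T2 (hypoexponential)
            a, b = rates[0], rates[1]
            return a * b / (b - a) * (np.exp(-a * u) - np.exp(-b * u))

        ref = quad(
            lambda u: density_sum2(u) * np.exp(-rates[2] * (t - u)), 0, t
        )[0]
        assert likelihood(net, Profile([1, 1, 0]), t) == pytest.approx(ref, rel=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            likelihood(HazardNetwork([[1.0]]), Profile([1]), -0.1)


class TestExpectedTime:
    def test_symmetric_two_event(self):
        assert expected_time(HazardNetwork(np.ones((2, 2))), Profile([1, 0])) == 1.0

    def test_absorbing_state_undefined(self):
        with pytest.raises(ExpectedTimeUndefinedError):
            expected_time(HazardNetwork([[2.0]]), Profile([1]))

    def test_matches_quadrature(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 6))
            net = random_network(rng, n)
            k = int(rng.integers(1, n))  # strict subset so the state decays
            p = random_profile(rng, n, k=k)
            sub = build_subspace_generator(net, p).generator

            def f(t):
                return expm(t * sub)[0, -1]

            num = quad(lambda t: t * f(t), 0, np.inf, limit=200)[0]
            den = quad(f, 0, np.inf, limit=200)[0]
            assert expected_time(net, p) == pytest.approx(num / den, rel=1e-6)


class TestStateDistribution:
    def test_t0_indicator(self, rng):
        net = random_network(rng, 4)
        d = state_distribution(net, 0.0)
        np.testing.assert_allclose(d, np.eye(16)[0], atol=1e-12)

    def test_single_event(self):
        d = state_distribution(HazardNetwork([[1.0]]), 1.0)
        np.testing.assert_allclose(d, [np.exp(-1), 1 - np.exp(-1)], atol=1e-12)

    @pytest.mark.parametrize("t", [0.1, 1.0, 10.0])
    def test_conservation(self, rng, t):
        for n in (3, 6, 9):
            net = random_network(rng, n)
            d = state_distribution(net, t)
            assert d.sum() == pytest.approx(1.0, abs=1e-9)
            assert (d >= -1e-12).all()
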