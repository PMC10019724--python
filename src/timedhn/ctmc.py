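"""Continuous-time Markov chain core for irreversible event accumulation.

The accumulation of ``n`` irreversible genetic events is modelled as a CTMC on
the ``2**n`` vertices of the binary hypercube.  A state is a binary profile
``x`` marking which events have occurred; transitions add exactly one event at
a time.  Rates are parameterized by an ``n x n`` hazard matrix ``R``:
``R[j, j]`` is the spontaneous occurrence rate of event ``j`` and ``R[i, j]``
(``i != j``) is the additional rate contributed to event ``j`` once event
``i`` has occurred, so the total rate of acquiring ``j`` in state ``x`` is
``R[j, j] + sum_i R[i, j] * x[i]`` (competing independent exponential clocks).

The likelihood of observing profile ``x`` at time ``t`` is the ``(normal
state, x)`` entry of ``exp(t Q)`` where ``Q`` is the ``2**n x 2**n``
generator.  Because the chain is monotone, that single entry only depends on
the ``2**k`` states componentwise below ``x`` (``k`` = number of accumulated
events), so it can be computed from the restriction of ``Q`` to that
sub-hypercube -- exponentially cheaper whenever profiles are sparse.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.linalg import expm, solve_triangular

__all__ = [
    "HazardNetwork",
    "Profile",
    "SubspaceSystem",
    "FullGenerator",
    "dec_index",
    "transition_rate",
    "build_full_generator",
    "subspace_index_map",
    "build_subspace_generator",
    "likelihood",
    "expected_time",
    "state_distribution",
    "ExpectedTimeUndefinedError",
    "ORACLE_N_CAP",
    "DEFAULT_K_MAX",
]

#: Largest n for which full 2**n-state operations are allowed (oracle guard).
ORACLE_N_CAP = 12

#: Largest number of accumulated events a subspace computation will accept.
DEFAULT_K_MAX = 20


class ExpectedTimeUndefinedError(ValueError):
    """The conditional time expectation does not exist for this profile.

    Raised when the observed state has zero total exit rate (e.g. the fully
    aberrant state): its occupancy probability does not decay, so the
    defining integrals diverge.
    """


class HazardNetwork:
    """Weighted directed graph of pairwise hazard dependencies.

    Parameters
    ----------
    rates : (n, n) array_like of nonnegative floats
        Hazard rate matrix ``R``.  Diagonal entries are spontaneous rates
        (units: events per unit time); off-diagonal ``R[i, j]`` is the extra
        rate on event ``j`` contributed by an already-occurred event ``i``.
    event_names : sequence of str, optional
        Identifiers for the ``n`` events; defaults to ``e0 .. e{n-1}``.
    """

    __slots__ = ("rates", "event_names")

    def __init__(self, rates, event_names=None):
        rates = np.asarray(rates, dtype=float)
        if rates.ndim != 2 or rates.shape[0] != rates.shape[1]:
            raise ValueError(f"rates must be a square matrix, got shape {rates.shape}")
        if not np.all(np.isfinite(rates)):
            raise ValueError("hazard rates must be finite")
        if np.any(rates < 0):
            raise ValueError("hazard rates must be nonnegative")
        self.rates = rates
        n = rates.shape[0]
        if event_names is None:
            event_names = [f"e{i}" for i in range(n)]
        event_names = list(event_names)
        if len(event_names) != n:
            raise ValueError(f"expected {n} event names, got {len(event_names)}")
        self.event_names = event_names

    @property
    def n(self) -> int:
        return self.rates.shape[0]

    def scaled(self, s: float) -> "HazardNetwork":
        """Return a copy with all rates multiplied by ``s`` (gauge scaling)."""
        return HazardNetwork(self.rates * s, self.event_names)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"HazardNetwork(n={self.n})"


class Profile:
    """A binary event profile: one vertex of the n-hypercube.

    Attributes
    ----------
    bits : (n,) uint8 ndarray
        The profile vector ``x``.
    k : int
        Number of accumulated events, ``sum(bits)``.
    active : tuple of int
        Sorted 0-based indices of the occurred events.
    """

    __slots__ = ("bits", "active")

    def __init__(self, bits):
        bits = np.asarray(bits)
        if bits.ndim != 1:
            raise ValueError("profile bits must be a 1-D vector")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("profile bits must be 0/1")
        self.bits = bits.astype(np.uint8)
        self.bits.flags.writeable = False
        self.active = tuple(int(i) for i in np.flatnonzero(self.bits))

    @property
    def n(self) -> int:
        return self.bits.shape[0]

    @property
    def k(self) -> int:
        return len(self.active)

    def __eq__(self, other):
        return isinstance(other, Profile) and np.array_equal(self.bits, other.bits)

    def __hash__(self):
        return hash((self.n, self.active))

    def __repr__(self):
        return "Profile(" + "".join(map(str, self.bits)) + ")"


@dataclass(frozen=True)
class FullGenerator:
    """Full 2**n-state generator; a testing oracle for small ``n``."""

    n: int
    Q: np.ndarray


@dataclass(frozen=True)
class SubspaceSystem:
    """The restriction of the chain to the sub-hypercube below a profile.

    ``full_indices[i]`` is the 1-based full-space index (``dec``) of the
    i-th sub-state; ``generator`` is the restricted generator ``Q~`` whose
    diagonal keeps the *full-space* exit rates, so probability mass
    legitimately leaks out of the subspace.
    """

    profile: Profile
    full_indices: np.ndarray
    generator: np.ndarray

    @property
    def k(self) -> int:
        return self.profile.k


def dec_index(profile: Profile) -> int:
    """1-based hypercube index of a profile: ``x . (2**0, ..., 2**(n-1)) + 1``."""
    bits = profile.bits
    return int(bits @ (1 << np.arange(bits.shape[0], dtype=object))) + 1


def transition_rate(network: HazardNetwork, from_profile: Profile, j: int) -> float:
    """Rate of acquiring event ``j`` (0-based) in state ``from_profile``.

    Equals ``R[j, j] + sum_i R[i, j] * x[i]``.  Raises if event ``j`` has
    already occurred (events are irreversible).
    """
    if not 0 <= j < network.n:
        raise IndexError(f"event index {j} out of range for n={network.n}")
    if from_profile.bits[j]:
        raise ValueError(f"event {j} already occurred; transitions are irreversible")
    R = network.rates
    return float(R[j, j] + from_profile.bits @ R[:, j])


def _state_rates(R: np.ndarray, bits_matrix: np.ndarray) -> np.ndarray:
    """Acquisition rates of every event in every row-state of ``bits_matrix``.

    Returns an (m, n) matrix whose [a, j] entry is the rate of event j in
    state a (meaningful where bits_matrix[a, j] == 0).
    """
    return np.diag(R)[None, :] + bits_matrix @ R


def build_full_generator(network: HazardNetwork, cap: int = ORACLE_N_CAP) -> FullGenerator:
    """Dense 2**n x 2**n generator; guarded by ``cap`` against state blow-up."""
    n = network.n
    if n > cap:
        raise ValueError(f"n={n} exceeds the full-space oracle cap {cap}")
    size = 1 << n
    states = ((np.arange(size)[:, None] >> np.arange(n)[None, :]) & 1).astype(float)
    rates = _state_rates(network.rates, states)
    Q = np.zeros((size, size))
    for j in range(n):
        absent = np.flatnonzero(states[:, j] == 0)
        Q[absent, absent + (1 << j)] = rates[absent, j]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return FullGenerator(n=n, Q=Q)


def subspace_index_map(profile: Profile) -> np.ndarray:
    """1-based full-space indices of the ``2**k`` sub-states of a profile.

    Sub-state ``i`` (1-based) activates the subset of the profile's events
    encoded by the binary digits of ``i - 1``; its full index is
    ``bit_k(i-1) . b_sub + 1`` with ``b_sub = (2**m_1, ..., 2**m_k)``.
    Entry 1 is the normal state and entry ``2**k`` is ``dec(profile)``.
    """
    active = np.asarray(profile.active, dtype=np.int64)
    k = active.shape[0]
    sub = np.arange(1 << k, dtype=np.int64)
    digits = (sub[:, None] >> np.arange(k)[None, :]) & 1
    return digits @ (np.int64(1) << active) + 1


@lru_cache(maxsize=4096)
def _subspace_structure(n: int, active: tuple):
    """Cached structural data of the sub-hypercube below a profile.

    Returns (bits_matrix, trans_rows, trans_cols, trans_events) where
    bits_matrix is (2**k, n) with the full bit pattern of every sub-state and
    the transition triplets list every one-event move inside the subspace
    (row sub-state, column sub-state, acquired event).
    """
    k = len(active)
    m = 1 << k
    sub = np.arange(m, dtype=np.int64)
    digits = ((sub[:, None] >> np.arange(max(k, 1))[None, :]) & 1)[:, :k]
    bits_matrix = np.zeros((m, n), dtype=np.uint8)
    if k:
        bits_matrix[:, list(active)] = digits.astype(np.uint8)
    rows, cols, events = [], [], []
    for p, ev in enumerate(active):
        a = np.flatnonzero((sub >> p) & 1 == 0)
        rows.append(a)
        cols.append(a + (1 << p))
        events.append(np.full(a.shape[0], ev, dtype=np.int64))
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        events = np.concatenate(events)
    else:
        rows = cols = events = np.zeros(0, dtype=np.int64)
    for arr in (bits_matrix, rows, cols, events):
        arr.flags.writeable = False
    return bits_matrix, rows, cols, events


def _subspace_generator_matrix(R: np.ndarray, n: int, active: tuple) -> np.ndarray:
    """Numeric Q~ for the cached structure under hazard matrix ``R``."""
    bits_matrix, rows, cols, events = _subspace_structure(n, active)
    m = bits_matrix.shape[0]
    rates = _state_rates(R, bits_matrix.astype(float))
    Qs = np.zeros((m, m))
    Qs[rows, cols] = rates[rows, events]
    # Diagonal = minus the *full-space* exit rate: every absent event of the
    # sub-state counts, including events outside the profile's active set.
    exit_rates = np.where(bits_matrix == 0, rates, 0.0).sum(axis=1)
    Qs[np.arange(m), np.arange(m)] = -exit_rates
    return Qs


def build_subspace_generator(
    network: HazardNetwork, profile: Profile, k_max: int = DEFAULT_K_MAX
) -> SubspaceSystem:
    """Restricted generator of the sub-hypercube componentwise below ``profile``.

    The sub-states are ordered by their sub-index (subsets of the active
    events in binary-counter order), which makes ``Q~`` upper triangular.
    Identical to the leading principal submatrix obtained by the column
    permutation that maps the subspace to the front of the full generator.
    """
    if profile.n != network.n:
        raise ValueError("profile and network disagree on n")
    if profile.k > k_max:
        raise ValueError(f"profile has k={profile.k} accumulated events, above k_max={k_max}")
    Qs = _subspace_generator_matrix(network.rates, network.n, profile.active)
    return SubspaceSystem(
        profile=profile,
        full_indices=subspace_index_map(profile),
        generator=Qs,
    )


def likelihood(
    network: HazardNetwork, profile: Profile, t: float, k_max: int = DEFAULT_K_MAX
) -> float:
    """P(x, t): probability of occupying ``profile`` at time ``t`` from normal.

    Computed as entry ``(1, 2**k)`` of ``exp(t Q~)`` in the profile's
    subspace, which equals the ``(1, dec(x))`` entry of the full ``exp(t Q)``.
    """
    if t < 0:
        raise ValueError(f"time must be nonnegative, got {t}")
    subsys = build_subspace_generator(network, profile, k_max=k_max)
    value = float(expm(t * subsys.generator)[0, -1])
    # expm roundoff can leave harmless epsilon-scale excursions outside [0, 1]
    return min(max(value, 0.0), 1.0)


def expected_time(
    network: HazardNetwork, profile: Profile, k_max: int = DEFAULT_K_MAX
) -> float:
    """Conditional expected observation time E(t | x).

    The time of an observation with profile ``x`` under a flat prior on t:

        E(t|x) = int_0^inf t P(x,t) dt / int_0^inf P(x,t) dt
               = (Q~^-2)_{1, 2**k} / (-Q~^-1)_{1, 2**k},

    using ``int_0^inf exp(tA) dt = -A^-1`` for a decaying entry.  Undefined
    (raises :class:`ExpectedTimeUndefinedError`) when the profile state has
    zero total exit rate, e.g. the fully aberrant state.
    """
    subsys = build_subspace_generator(network, profile, k_max=k_max)
    Qs = subsys.generator
    diag = np.diag(Qs)
    if diag[-1] == 0.0:
        raise ExpectedTimeUndefinedError(
            "profile has zero exit rate; occupancy never decays and E(t|x) diverges"
        )
    if np.any(diag == 0.0):
        raise ExpectedTimeUndefinedError(
            "an intermediate sub-state has zero exit rate; Q~ is singular"
        )
    m = Qs.shape[0]
    e1 = np.zeros(m)
    e1[0] = 1.0
    # first row of Q~^-1 and last column of Q~^-1 via triangular solves
    inv_row1 = solve_triangular(Qs, e1, trans="T", lower=False)
    elast = np.zeros(m)
    elast[-1] = 1.0
    inv_collast = solve_triangular(Qs, elast, lower=False)
    numerator = float(inv_row1 @ inv_collast)  # (Q~^-2)_{1, 2**k}
    denominator = float(-inv_row1[-1])  # (-Q~^-1)_{1, 2**k}
    if denominator <= 0 or not np.isfinite(numerator / denominator):
        raise ExpectedTimeUndefinedError("conditional expectation is not finite")
    return numerator / denominator


def state_distribution(
    network: HazardNetwork, t: float, cap: int = ORACLE_N_CAP
) -> np.ndarray:
    """Occupancy distribution over all 2**n states at time ``t`` (oracle)."""
    if t < 0:
        raise ValueError(f"time must be nonnegative, got {t}")
    full = build_full_generator(network, cap=cap)
    return expm(t * full.Q)[0]
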