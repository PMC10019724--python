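"""Synthetic benchmark data: random hazard networks and CTMC-sampled profiles.

The generator reproduces a standard benchmark protocol for oncogenetic
graph-recovery methods: draw a random forest- or DAG-structured hazard
network, simulate event-accumulation trajectories from it with a Gillespie
sampler capped at a maximum number of jumps (tumours rarely accumulate more
than ~10 driver events), observe each trajectory at a uniformly random time
before the cap, and optionally corrupt the observed profiles with
independent per-event bit flips.

Conventions baked into the defaults: all inter-event edge weights are 1,
source nodes (no incoming edge) have spontaneous rate 1, every other node
has spontaneous rate 0.1, forests have maximum depth ``floor(log2(n))`` with
every depth occupied, and DAGs have exactly ``floor(1.5 n)`` edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ctmc import HazardNetwork, Profile, _state_rates
from .inference import Dataset

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "random_forest_network",
    "random_dag_network",
    "sample_trajectory",
    "sample_profile",
    "apply_noise",
    "noise_ladder",
    "generate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``max_events`` caps the number of jumps per trajectory at
    ``min(max_events, n)``; observation times are uniform on ``[0, T]`` with
    ``T`` the time of the capped jump, which keeps observed profiles sparse.
    """

    n: int
    topology: str = "forest"  # "forest" | "dag"
    sample_size: int = 250
    max_events: int = 10
    noise_prob: float = 0.0
    seed: int | None = None
    edge_weight: float = 1.0
    source_rate: float = 1.0
    nonsource_rate: float = 0.1
    depth_log_base: float = 2.0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need at least 2 events")
        if self.topology not in ("forest", "dag"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        if not 0 <= self.noise_prob < 1:
            raise ValueError("noise_prob must be in [0, 1)")
        object.__setattr__(self, "max_events", min(self.max_events, self.n))


@dataclass(frozen=True)
class GroundTruth:
    """The simulated hazard network and its binary edge structure."""

    network: HazardNetwork
    adjacency: np.ndarray  # binary off-diagonal edge indicator
    topology: str


def _network_from_edges(
    n: int, edges: list[tuple[int, int]], config: SimulationConfig
) -> GroundTruth:
    adjacency = np.zeros((n, n), dtype=np.int8)
    R = np.zeros((n, n))
    for i, j in edges:
        adjacency[i, j] = 1
        R[i, j] = config.edge_weight
    is_source = adjacency.sum(axis=0) == 0
    np.fill_diagonal(
        R, np.where(is_source, config.source_rate, config.nonsource_rate)
    )
    return GroundTruth(
        network=HazardNetwork(R), adjacency=adjacency, topology=config.topology
    )


def random_forest_network(
    n: int, config: SimulationConfig, rng: np.random.Generator
) -> GroundTruth:
    """Random forest: nodes at random depths, one parent from the level above.

    Depths run from 1 to ``floor(log_b(n))`` (base ``depth_log_base``, 2 by
    default) and every depth is occupied; depth-1 nodes are roots.
    """
    if n < 2:
        raise ValueError("need at least 2 events for a forest")
    max_depth = max(int(math.floor(math.log(n, config.depth_log_base))), 1)
    # Guarantee every depth is occupied, then assign the rest uniformly.
    order = rng.permutation(n)
    depths = np.empty(n, dtype=np.int64)
    depths[order[:max_depth]] = np.arange(1, max_depth + 1)
    depths[order[max_depth:]] = rng.integers(1, max_depth + 1, size=n - max_depth)
    edges = []
    for node in range(n):
        d = depths[node]
        if d > 1:
            parents = np.flatnonzero(depths == d - 1)
            edges.append((int(rng.choice(parents)), node))
    truth = _network_from_edges(n, edges, config)
    return GroundTruth(truth.network, truth.adjacency, "forest")


def random_dag_network(
    n: int, config: SimulationConfig, rng: np.random.Generator
) -> GroundTruth:
    """Random DAG: a topological order plus ``floor(1.5 n)`` order-respecting edges."""
    n_edges = int(math.floor(1.5 * n))
    if n_edges > n * (n - 1) // 2:
        raise ValueError(
            f"cannot place {n_edges} acyclic edges among {n} nodes "
            f"(max {n * (n - 1) // 2})"
        )
    rank = rng.permutation(n)  # rank[i] = topological position of node i
    # All order-respecting candidate pairs, sampled without replacement.
    candidates = [
        (i, j)
        for i in range(n)
        for j in range(n)
        if i != j and rank[i] < rank[j]
    ]
    chosen = rng.choice(len(candidates), size=n_edges, replace=False)
    edges = [candidates[c] for c in chosen]
    truth = _network_from_edges(n, edges, config)
    return GroundTruth(truth.network, truth.adjacency, "dag")


def sample_trajectory(
    network: HazardNetwork, max_events: int, rng: np.random.Generator
):
    """One Gillespie run from the normal state, stopped after ``max_events`` jumps.

    Returns ``(jump_times, states)`` where ``states`` has ``max_events + 1``
    bit vectors (the normal state first) and ``jump_times`` the strictly
    increasing times of the ``max_events`` jumps.
    """
    n = network.n
    if max_events > n:
        raise ValueError(f"max_events={max_events} exceeds n={n}")
    R = network.rates
    bits = np.zeros(n, dtype=np.uint8)
    states = [bits.copy()]
    times = []
    t = 0.0
    for _ in range(max_events):
        rates = _state_rates(R, bits[None, :].astype(float))[0]
        rates = np.where(bits == 0, rates, 0.0)
        total = rates.sum()
        if total <= 0:
            raise RuntimeError(
                "trajectory stuck: zero total exit rate before the jump cap"
            )
        t += rng.exponential(1.0 / total)
        j = rng.choice(n, p=rates / total)
        bits[j] = 1
        times.append(t)
        states.append(bits.copy())
    return np.array(times), states


def sample_profile(
    network: HazardNetwork, max_events: int, rng: np.random.Generator
):
    """Observe one trajectory at a uniform time before its capped jump.

    ``T`` is the time of the ``max_events``-th jump and ``t ~ U[0, T]``; the
    returned profile is the trajectory's state at ``t`` (so ``k < max_events``
    almost surely, and the accumulated count never exceeds the cap).
    """
    times, states = sample_trajectory(network, max_events, rng)
    T = times[-1]
    t = rng.uniform(0.0, T)
    k = int(np.searchsorted(times, t, side="right"))
    return Profile(states[k]), float(t)


def apply_noise(profile: Profile, p: float, rng: np.random.Generator) -> Profile:
    """Flip each event independently with probability ``p`` (symmetric noise)."""
    if not 0 <= p < 1:
        raise ValueError("flip probability must be in [0, 1)")
    flips = rng.random(profile.n) < p
    return Profile(np.where(flips, 1 - profile.bits, profile.bits))


def noise_ladder(
    profiles: list[Profile], levels: list[float], rng: np.random.Generator
) -> dict[float, list[Profile]]:
    """Corrupt the same profiles at several noise levels with nested flips.

    A single uniform draw per bit is thresholded at each level, so the flip
    sets are monotone in ``p`` (every flip at a lower level also occurs at
    every higher level).  This couples the noisy datasets and removes
    between-level sampling noise when comparing robustness across levels.
    """
    out: dict[float, list[Profile]] = {p: [] for p in levels}
    for profile in profiles:
        u = rng.random(profile.n)
        for p in levels:
            flips = u < p
            out[p].append(Profile(np.where(flips, 1 - profile.bits, profile.bits)))
    return out


def generate_dataset(config: SimulationConfig):
    """Draw a network and an i.i.d. synthetic dataset from it.

    Returns ``(dataset, truth)``; the dataset carries the true observation
    times.  The network, the trajectory sampling, and the noise use separate
    RNG streams derived from the seed, so the clean and noisy versions of a
    dataset are pairable.
    """
    ss = np.random.SeedSequence(config.seed)
    net_rng, samp_rng, noise_rng = (np.random.default_rng(c) for c in ss.spawn(3))
    if config.topology == "forest":
        truth = random_forest_network(config.n, config, net_rng)
    else:
        truth = random_dag_network(config.n, config, net_rng)
    profiles, times = [], []
    for _ in range(config.sample_size):
        prof, t = sample_profile(truth.network, config.max_events, samp_rng)
        profiles.append(prof)
        times.append(t)
    if config.noise_prob > 0:
        profiles = [apply_noise(p, config.noise_prob, noise_rng) for p in profiles]
    dataset = Dataset(
        profiles=profiles,
        sample_ids=[f"s{i}" for i in range(config.sample_size)],
        times=np.array(times),
        event_names=truth.network.event_names,
    )
    return dataset, truth
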