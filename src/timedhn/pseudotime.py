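"""Post-fit temporal analysis: event orders and sample progression times.

Two orderings come out of a fitted hazard network.  Per profile, the
maximum-likelihood *accumulation order* of its events is found by brute
force over all ``k!`` permutations, scoring each by its embedded jump-chain
probability (the product over steps of ``rate of the chosen event / total
exit rate of the current state``) -- a time-free quantity.  Per dataset,
samples are ranked by the conditional expected progression time ``E(t|x)``,
which serves as a model-based pseudo-time for cross-sectional profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .ctmc import (
    ExpectedTimeUndefinedError,
    HazardNetwork,
    Profile,
    _state_rates,
    dec_index,
    expected_time,
)

logger = logging.getLogger(__name__)

__all__ = [
    "OrderResult",
    "order_probability",
    "ml_accumulation_order",
    "order_samples",
    "pseudotime_table",
    "BRUTE_FORCE_K_CAP",
]

#: Largest k for which the k! order enumeration is attempted (9! = 362880).
BRUTE_FORCE_K_CAP = 9


@dataclass(frozen=True)
class OrderResult:
    """Best accumulation order of one profile's events."""

    profile: Profile
    best_order: tuple
    best_prob: float
    expected_time: float | None
    all_probs: dict | None = None


def order_probability(network: HazardNetwork, order) -> float:
    """Embedded jump-chain probability of acquiring events in ``order``.

    The product over steps of (rate of the chosen event in the current
    state) / (total exit rate of the current state).  A zero-rate step gives
    probability 0.  Orders over all subsets and lengths form a proper
    distribution: summed over all complete orders the probabilities reach 1.
    """
    order = [int(j) for j in order]
    if len(set(order)) != len(order):
        raise ValueError("order must not repeat events")
    n = network.n
    bits = np.zeros(n)
    prob = 1.0
    for j in order:
        if not 0 <= j < n:
            raise IndexError(f"event {j} out of range")
        if bits[j]:
            raise ValueError("order revisits an already-acquired event")
        rates = _state_rates(network.rates, bits[None, :])[0]
        rates = np.where(bits == 0, rates, 0.0)
        total = rates.sum()
        if total <= 0 or rates[j] <= 0:
            return 0.0
        prob *= rates[j] / total
        bits[j] = 1.0
    return prob


def ml_accumulation_order(
    network: HazardNetwork,
    profile: Profile,
    cap: int = BRUTE_FORCE_K_CAP,
    keep_all: bool = False,
) -> OrderResult:
    """Brute-force search over all k! accumulation orders of a profile.

    Ties are broken deterministically toward the lexicographically smallest
    order.  Attaches ``E(t|x)`` (None when undefined, e.g. the fully
    aberrant state).
    """
    if profile.k > cap:
        raise ValueError(f"k={profile.k} exceeds the brute-force cap {cap}")
    best_order = profile.active
    best_prob = -1.0
    all_probs = {} if keep_all else None
    for order in permutations(profile.active):
        p = order_probability(network, order)
        if keep_all:
            all_probs[order] = p
        if p > best_prob:  # strict: first (lexicographic) order wins ties
            best_order, best_prob = order, p
    try:
        etime = expected_time(network, profile)
    except ExpectedTimeUndefinedError:
        etime = None
    return OrderResult(
        profile=profile,
        best_order=tuple(best_order),
        best_prob=float(best_prob),
        expected_time=etime,
        all_probs=all_probs,
    )


def order_samples(network: HazardNetwork, dataset) -> list:
    """Rank samples by conditional expected progression time, ascending.

    Returns a list of ``(sample_id, profile, expected_time)`` tuples; ties
    break by (k, hypercube index, sample id).  Profiles whose expectation is
    undefined are flagged with ``None`` and ranked last.
    """
    etime_cache: dict = {}
    records = []
    for sid, profile in zip(dataset.sample_ids, dataset.profiles):
        key = profile.active
        if key not in etime_cache:
            try:
                etime_cache[key] = expected_time(network, profile)
            except ExpectedTimeUndefinedError:
                logger.warning(
                    "E(t|x) undefined for sample %s (profile %s); ranked last",
                    sid,
                    profile,
                )
                etime_cache[key] = None
        records.append((sid, profile, etime_cache[key]))
    records.sort(
        key=lambda r: (
            r[2] is None,
            r[2] if r[2] is not None else 0.0,
            r[1].k,
            dec_index(r[1]),
            r[0],
        )
    )
    return records


def pseudotime_table(network: HazardNetwork, dataset, cap: int = BRUTE_FORCE_K_CAP):
    """Per-sample pseudo-time report as a DataFrame.

    One row per sample, ranked by ``E(t|x)``: profile bits, accumulated
    count, maximum-likelihood accumulation order (event names joined by
    arrows), its jump-chain probability, and the expected progression time.
    """
    names = network.event_names
    order_cache: dict = {}
    rows = []
    for sid, profile, etime in order_samples(network, dataset):
        key = profile.active
        if key not in order_cache:
            if profile.k <= cap:
                order_cache[key] = ml_accumulation_order(network, profile, cap=cap)
            else:
                order_cache[key] = None
        res = order_cache[key]
        rows.append(
            {
                "sample_id": sid,
                "profile": "".join(map(str, profile.bits)),
                "k": profile.k,
                "ml_order": (
                    "→".join(names[j] for j in res.best_order)
                    if res is not None
                    else ""
                ),
                "order_prob": res.best_prob if res is not None else np.nan,
                "expected_time": etime if etime is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)
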