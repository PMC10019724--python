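"""Constrained maximum-likelihood estimation of the hazard network.

The estimation problem: given cross-sectional binary profiles
``x_1, .., x_|D|`` with (known or unknown) progression times ``t_i``,
maximize the regularized average log-likelihood

    (1/|D|) sum_i log (exp(t_i Q))_{1, dec(x_i)}  -  lambda * sum_ij |R_ij|

subject to ``R >= 0``, ``t >= 0`` and ``||t||_1 = c``.  The time-budget
constraint fixes the scale gauge: the likelihood only depends on the product
``t Q``, so rescaling rates up and times down is unidentifiable without it.
Rates are rectified by projection (clipped at zero after every step; with
the L1 subgradient taken as 0 at 0, unsupported entries stay exactly zero,
which yields genuinely sparse networks) and times are projected onto the
simplex-like constraint set after every step.

Gradients are exact (see :mod:`timedhn.gradients`); the loop batches the
per-sample matrix exponentials by subspace size through
:mod:`timedhn._engine`.  Samples with identical profiles share one cached
subspace; under joint time inference their times receive identical updates
from identical initializations, so they are carried as a single group
without changing the per-sample dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from ._engine import expm_frechet_batched
from .ctmc import (
    DEFAULT_K_MAX,
    HazardNetwork,
    Profile,
    _subspace_generator_matrix,
    _subspace_structure,
    likelihood as _likelihood,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Dataset",
    "FitConfig",
    "FitResult",
    "objective",
    "project_times",
    "fit",
    "threshold_network",
]

_LIKELIHOOD_FLOOR = 1e-300
#: Spontaneous rates are kept at least this positive so that every profile
#: stays reachable (zero spontaneous rate would make some likelihoods exactly
#: zero and the objective -inf).  Negligible against the O(0.1-1) fitted rates.
_DIAG_FLOOR = 1e-8


@dataclass
class Dataset:
    """Cross-sectional profiles with optional per-sample progression times."""

    profiles: list
    sample_ids: list
    times: np.ndarray | None = None
    event_names: list | None = None

    def __post_init__(self):
        if not self.profiles:
            raise ValueError("dataset is empty")
        n = self.profiles[0].n
        if any(p.n != n for p in self.profiles):
            raise ValueError("all profiles must share the same number of events")
        if len(self.sample_ids) != len(self.profiles):
            raise ValueError("sample_ids and profiles length mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (len(self.profiles),):
                raise ValueError("times must align with profiles")
            if np.any(self.times < 0):
                raise ValueError("times must be nonnegative")
        if self.event_names is None:
            self.event_names = [f"e{i}" for i in range(n)]
        elif len(self.event_names) != n:
            raise ValueError("event_names length mismatch")

    @property
    def n(self) -> int:
        return self.profiles[0].n

    def __len__(self) -> int:
        return len(self.profiles)

    @classmethod
    def from_matrix(cls, X, sample_ids=None, times=None, event_names=None):
        """Build a dataset from a (samples x events) 0/1 matrix."""
        X = np.asarray(X)
        if sample_ids is None:
            sample_ids = [f"s{i}" for i in range(X.shape[0])]
        profiles = [Profile(row) for row in X]
        return cls(
            profiles=profiles,
            sample_ids=list(sample_ids),
            times=times,
            event_names=event_names,
        )

    def matrix(self) -> np.ndarray:
        return np.stack([p.bits for p in self.profiles]).astype(np.int8)


@dataclass(frozen=True)
class FitConfig:
    """Hyperparameters and constraints of the MLE problem.

    ``time_budget`` is the constant ``c`` in ``||t||_1 = c``; it defaults to
    ``|D|`` (mean time 1), which only fixes the gauge.  ``times_mode`` is
    ``"joint"`` (times are trainable) or ``"fixed"`` (pseudo-times supplied
    with the data; rescaled to sum ``c`` unless ``rescale_fixed_times`` is
    off).  ``optimizer`` is ``"gd"`` (plain fixed-step ascent, optionally
    with step halving on objective decrease) or ``"adam"``.
    """

    lam: float = 1e-2
    learning_rate: float = 1e-3
    max_iter: int = 5000
    tol: float = 1e-7
    time_budget: float | None = None
    times_mode: str = "joint"
    threshold_frac: float = 0.1
    seed: int = 0
    k_max: int = DEFAULT_K_MAX
    time_floor_scale: float = 1e-6
    optimizer: str = "gd"
    step_halving: bool = True
    rescale_fixed_times: bool = True
    init_rates: np.ndarray | None = None
    init_times: np.ndarray | None = None

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.time_budget is not None and self.time_budget <= 0:
            raise ValueError("time_budget must be > 0")
        if not 0 <= self.threshold_frac < 1:
            raise ValueError("threshold_frac must be in [0, 1)")
        if self.times_mode not in ("joint", "fixed"):
            raise ValueError(f"unknown times_mode {self.times_mode!r}")
        if self.optimizer not in ("gd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class FitResult:
    """Outcome of one constrained-MLE run."""

    network: HazardNetwork
    times: np.ndarray
    objective_trace: np.ndarray
    config: FitConfig
    converged: bool
    iterations: int
    sample_ids: list | None = None


def objective(
    network: HazardNetwork,
    dataset: Dataset,
    times: np.ndarray,
    lam: float,
    k_max: int = DEFAULT_K_MAX,
) -> float:
    """Regularized average log-likelihood (the quantity `fit` ascends)."""
    times = np.asarray(times, dtype=float)
    if times.shape != (len(dataset),):
        raise ValueError("times must align with the dataset")
    total = 0.0
    for sid, profile, t in zip(dataset.sample_ids, dataset.profiles, times):
        value = _likelihood(network, profile, float(t), k_max=k_max)
        if value <= 0:
            logger.warning("sample %s has zero likelihood at t=%g", sid, t)
            return -np.inf
        total += np.log(value)
    return total / len(dataset) - lam * np.abs(network.rates).sum()


def project_times(times: np.ndarray, c: float, epsilon: float = 1e-12) -> np.ndarray:
    """Clip times below at ``epsilon`` then rescale to L1 norm exactly ``c``."""
    if c <= 0:
        raise ValueError("time budget c must be > 0")
    times = np.asarray(times, dtype=float)
    clipped = np.maximum(times, epsilon)
    total = clipped.sum()
    if total <= 0:  # all-zero input with epsilon = 0
        return np.full_like(times, c / times.shape[0])
    return clipped * (c / total)


def threshold_network(network: HazardNetwork, frac: float):
    """Post-hoc pruning: drop off-diagonal rates below ``frac * max(R)``.

    Returns ``(adjacency, pruned)``: the binary directed edge indicator used
    for structure scoring and the pruned weighted network.  Spontaneous
    (diagonal) rates are never pruned.
    """
    if not 0 <= frac < 1:
        raise ValueError("threshold fraction must be in [0, 1)")
    R = network.rates
    cutoff = frac * R.max() if R.size else 0.0
    pruned = R.copy()
    off = ~np.eye(network.n, dtype=bool)
    pruned[off & (R < cutoff)] = 0.0
    adjacency = ((pruned > 0) & off).astype(np.int8)
    return adjacency, HazardNetwork(pruned, network.event_names)


# ----------------------------------------------------------------------------
# fit internals


class _SampleGroup:
    """Samples sharing one subspace (and, in joint mode, one time variable)."""

    __slots__ = ("profile", "count", "t", "member_idx", "m", "gather", "smap")

    def __init__(self, profile: Profile, n: int):
        self.profile = profile
        self.count = 0
        self.t = 0.0
        self.member_idx: list[int] = []
        self.m = 1 << profile.k
        self._build_structural_map(n)

    def _build_structural_map(self, n: int):
        """Flat gather indices into dL/dQ~ and the signed chain-rule matrix.

        ``gather`` lists the positions of Q~'s structural nonzeros
        (transitions first, then the diagonal); ``smap`` maps the gathered
        derivative values to dL/dR, including the negative diagonal
        (exit-rate) contributions of every absent event.
        """
        bits_matrix, rows, cols, events = _subspace_structure(n, self.profile.active)
        m = self.m
        self.gather = np.concatenate([rows * m + cols, np.arange(m) * (m + 1)])
        coo_r, coo_c, coo_v = [], [], []
        # transition entries: +1 on R[j,j], +y_i on R[i,j]
        for pos, (a, j) in enumerate(zip(rows, events)):
            coo_r.append(j * n + j)
            coo_c.append(pos)
            coo_v.append(1.0)
            for i in np.flatnonzero(bits_matrix[a]):
                coo_r.append(i * n + j)
                coo_c.append(pos)
                coo_v.append(1.0)
        # diagonal entries: -1 on R[j,j], -y_i on R[i,j] for every absent j
        base = rows.shape[0]
        for a in range(m):
            actives = np.flatnonzero(bits_matrix[a])
            for j in np.flatnonzero(bits_matrix[a] == 0):
                coo_r.append(j * n + j)
                coo_c.append(base + a)
                coo_v.append(-1.0)
                for i in actives:
                    coo_r.append(i * n + j)
                    coo_c.append(base + a)
                    coo_v.append(-1.0)
        self.smap = sparse.csr_matrix(
            (coo_v, (coo_r, coo_c)), shape=(n * n, base + m)
        )


def _make_groups(dataset: Dataset, times: np.ndarray, joint: bool):
    groups: dict = {}
    for idx, profile in enumerate(dataset.profiles):
        key = profile.active if joint else (profile.active, float(times[idx]))
        g = groups.get(key)
        if g is None:
            g = groups[key] = _SampleGroup(profile, dataset.n)
        g.count += 1
        g.t = float(times[idx])
        g.member_idx.append(idx)
    return list(groups.values())


def _batch_quantities(groups, R: np.ndarray, n: int):
    """Likelihood, dR- and dt-gradients for every group at hazard matrix R.

    Returns (values, dR_list, dt_list) aligned with ``groups``.  The Frechet
    derivative of exp at ``t Q~^T`` in direction ``E_{1,2**k}`` (the
    upper-right block of the doubled block matrix) is evaluated for all
    groups of equal subspace size in one vectorized call.
    """
    values = np.empty(len(groups))
    dts = np.empty(len(groups))
    dRs: list = [None] * len(groups)
    order = np.argsort([g.m for g in groups], kind="stable")
    pos = 0
    while pos < len(order):
        m = groups[order[pos]].m
        block = [i for i in order[pos:] if groups[i].m == m]
        pos += len(block)
        Qs_list = [
            _subspace_generator_matrix(R, n, groups[i].profile.active) for i in block
        ]
        A = np.stack([groups[i].t * Qs.T for i, Qs in zip(block, Qs_list)])
        E = np.zeros((m, m))
        E[0, m - 1] = 1.0
        F, L = expm_frechet_batched(A, E)
        for j, i in enumerate(block):
            g = groups[i]
            values[i] = F[j][m - 1, 0]  # (e^{tQ~})_{1, 2^k}
            dts[i] = F[j][m - 1] @ Qs_list[j][0]  # (Q~ e^{tQ~})_{1, 2^k}
            dQ = (g.t * L[j]).ravel()[g.gather]
            dRs[i] = (g.smap @ dQ).reshape(n, n)
    return values, dRs, dts


def fit(dataset: Dataset, config: FitConfig | None = None, callback=None) -> FitResult:
    """Projected-gradient ascent on the constrained MLE objective.

    Deterministic given ``config.seed``.  ``callback``, if given, is invoked
    as ``callback(iteration, R, times, objective)`` with the feasible iterate
    *before* each update (useful for monitoring the constraints).
    """
    config = config or FitConfig()
    n = dataset.n
    n_samples = len(dataset)
    kmax_obs = max(p.k for p in dataset.profiles)
    if kmax_obs > config.k_max:
        raise ValueError(
            f"a profile has k={kmax_obs} accumulated events, above k_max={config.k_max}"
        )
    c = config.time_budget if config.time_budget is not None else float(n_samples)
    eps = config.time_floor_scale * c / n_samples

    joint = config.times_mode == "joint"
    if joint:
        if config.init_times is not None:
            times0 = project_times(np.asarray(config.init_times, float), c, eps)
        else:
            times0 = np.full(n_samples, c / n_samples)
    else:
        if dataset.times is None:
            raise ValueError("times_mode='fixed' requires dataset.times")
        times0 = dataset.times.astype(float)
        if config.rescale_fixed_times:
            times0 = project_times(times0, c, eps)
        else:
            c = float(times0.sum())
    groups = _make_groups(dataset, times0, joint)
    counts = np.array([g.count for g in groups], dtype=float)

    rng = np.random.default_rng(config.seed)
    if config.init_rates is not None:
        W = np.array(config.init_rates, dtype=float, copy=True)
        if W.shape != (n, n):
            raise ValueError("init_rates must be an (n, n) matrix")
    else:
        W = 0.1 + rng.uniform(0.0, 0.01, size=(n, n))

    lr = config.learning_rate
    adam = config.optimizer == "adam"
    if adam:
        mW = np.zeros((n, n))
        vW = np.zeros((n, n))
        mT = np.zeros(len(groups))
        vT = np.zeros(len(groups))
        adam_step = 0

    def group_times():
        return np.array([g.t for g in groups])

    def expand(tg):
        out = np.empty(n_samples)
        for g, t in zip(groups, tg):
            out[g.member_idx] = t
        return out

    trace: list[float] = []
    converged = False
    # previously accepted iterate and its gradient step, for gd step-halving
    prev_point = None  # (W, tg)
    prev_step = None  # (gradW, per_sample_grad or None)
    iteration = 0
    while iteration < config.max_iter:
        R = np.maximum(W, 0.0)
        np.fill_diagonal(R, np.maximum(np.diag(R), _DIAG_FLOOR))
        values, dRs, dts = _batch_quantities(groups, R, n)
        clipped = np.maximum(values, _LIKELIHOOD_FLOOR)
        if np.any(values <= 0):
            bad = int(np.argmin(values))
            logger.warning(
                "likelihood underflow for profile %s (clamped)", groups[bad].profile
            )
        obj = float(counts @ np.log(clipped)) / n_samples - config.lam * np.abs(R).sum()

        if (
            config.optimizer == "gd"
            and config.step_halving
            and trace
            and obj < trace[-1] - 1e-12
            and prev_point is not None
        ):
            # Reject: retake the last accepted step with a halved rate.
            iteration += 1
            lr *= 0.5
            W_acc, tg_acc = prev_point
            gradW_acc, gradT_acc = prev_step
            W = W_acc + lr * gradW_acc
            if gradT_acc is not None:
                tg_full = project_times(expand(tg_acc + lr * gradT_acc), c, eps)
                for g in groups:
                    g.t = tg_full[g.member_idx[0]]
            else:
                for g, t in zip(groups, tg_acc):
                    g.t = t
            continue

        trace.append(obj)
        if callback is not None:
            callback(iteration, R.copy(), expand(group_times()), obj)
        if len(trace) >= 2:
            if abs(trace[-1] - trace[-2]) < config.tol * max(1.0, abs(trace[-2])):
                converged = True
                break

        # objective gradients
        weights = counts / (n_samples * clipped)
        gradW = -config.lam * np.sign(R)
        for w, dR in zip(weights, dRs):
            gradW += w * dR
        if not np.all(np.isfinite(gradW)):
            raise RuntimeError("non-finite gradient in R; aborting fit")
        # Rectified parameterization: entries at or below zero contribute no
        # rate, but a positive likelihood gradient may revive them (projected
        # ascent); with the L1 subgradient taken as 0 at 0, entries the data
        # do not support stay exactly zero.
        gradW = gradW * ((W > 0) | (gradW > 0))

        prev_point = (W.copy(), group_times())
        if adam:
            adam_step += 1
            mW = 0.9 * mW + 0.1 * gradW
            vW = 0.999 * vW + 0.001 * gradW**2
            mhat = mW / (1 - 0.9**adam_step)
            vhat = vW / (1 - 0.999**adam_step)
            W = np.maximum(W + lr * mhat / (np.sqrt(vhat) + 1e-8), 0.0)
        else:
            W = np.maximum(W + lr * gradW, 0.0)

        per_sample_grad = None
        if joint:
            # Every sample in a group has the same time variable and the same
            # per-sample gradient (1/(|D| L)) dL/dt, so stepping the shared
            # variable by that gradient reproduces the per-sample dynamics.
            per_sample_grad = dts / (n_samples * clipped)
            if not np.all(np.isfinite(per_sample_grad)):
                raise RuntimeError("non-finite gradient in t; aborting fit")
            if adam:
                mT = 0.9 * mT + 0.1 * per_sample_grad
                vT = 0.999 * vT + 0.001 * per_sample_grad**2
                mhatT = mT / (1 - 0.9**adam_step)
                vhatT = vT / (1 - 0.999**adam_step)
                tg = group_times() + lr * mhatT / (np.sqrt(vhatT) + 1e-8)
            else:
                tg = group_times() + lr * per_sample_grad
            tg_full = project_times(expand(tg), c, eps)
            for g in groups:
                g.t = tg_full[g.member_idx[0]]
        prev_step = (gradW, per_sample_grad)
        iteration += 1

    R = np.maximum(W, 0.0)
    np.fill_diagonal(R, np.maximum(np.diag(R), _DIAG_FLOOR))
    return FitResult(
        network=HazardNetwork(R, dataset.event_names),
        times=expand(group_times()),
        objective_trace=np.array(trace),
        config=config,
        converged=converged,
        iterations=iteration,
        sample_ids=list(dataset.sample_ids),
    )
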