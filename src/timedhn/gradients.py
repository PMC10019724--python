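"""Exact likelihood derivatives computed inside the profile subspace.

The sample likelihood is the scalar ``L = (exp(t Q~))_{1, 2**k}``.  Its
gradient with respect to every entry of ``Q~`` is obtained from a single
matrix exponential of the doubled block matrix

    B = [[t Q~^T, E_{1,2**k}],
        [0,      t Q~^T   ]],

whose upper-right block of ``exp(B)`` is the Frechet derivative of the
exponential at ``t Q~^T`` in the rank-one direction ``E_{1,2**k}``;
multiplying by ``t`` gives ``dL/dQ~`` entrywise.  The gradient with respect
to the hazard matrix ``R`` then follows by the chain rule through the
structural map of ``Q~``: each sub-transition rate is an affine function of
one column of ``R``, and each diagonal (exit-rate) entry references *all*
events absent in that sub-state -- including events outside the profile's
active set, which is why ``dL/dR`` has nonzeros outside the active submatrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .ctmc import (
    DEFAULT_K_MAX,
    HazardNetwork,
    Profile,
    SubspaceSystem,
    _subspace_structure,
    build_subspace_generator,
)

__all__ = [
    "LikelihoodGradient",
    "build_block_matrix",
    "expm_entry_derivative",
    "likelihood_grad_t",
    "likelihood_grad_R",
]


@dataclass(frozen=True)
class LikelihoodGradient:
    """Value and exact partials of one sample likelihood."""

    value: float
    dR: np.ndarray
    dt: float


def build_block_matrix(subsys: SubspaceSystem, t: float) -> np.ndarray:
    """Assemble the 2**(k+1) x 2**(k+1) augmented matrix B."""
    Qs = subsys.generator
    m = Qs.shape[0]
    B = np.zeros((2 * m, 2 * m))
    B[:m, :m] = t * Qs.T
    B[m:, m:] = t * Qs.T
    B[0, 2 * m - 1] = 1.0  # E_{1, 2**k} in the upper-right block
    return B


def expm_entry_derivative(
    subsys: SubspaceSystem, t: float, k_max: int = DEFAULT_K_MAX
) -> np.ndarray:
    """Matrix of partials d(exp(t Q~))_{1, 2**k} / dQ~[a, b].

    Extracted as ``t`` times the upper-right block of ``exp(B)``.  Entries
    below the diagonal correspond to structurally zero positions of ``Q~``
    and are computed but never consumed by the chain rule.
    """
    if subsys.k > k_max - 1:
        raise ValueError(
            f"block matrix doubles the dimension; k={subsys.k} exceeds k_max-1={k_max - 1}"
        )
    m = subsys.generator.shape[0]
    F = expm(build_block_matrix(subsys, t))
    return t * F[:m, m:]


def likelihood_grad_t(subsys: SubspaceSystem, t: float) -> float:
    """dL/dt = (Q~ exp(t Q~))_{1, 2**k}."""
    if t < 0:
        raise ValueError(f"time must be nonnegative, got {t}")
    Qs = subsys.generator
    return float((Qs @ expm(t * Qs))[0, -1])


def _contract_structural(
    dQ: np.ndarray, n: int, active: tuple
) -> np.ndarray:
    """Chain rule from dL/dQ~ to dL/dR through the structural map of Q~.

    For a sub-state y and an absent event j: the transition entry
    (y -> y+j, only when j is active in the profile) depends on R[j, j]
    with coefficient 1 and on R[i, j] with coefficient y_i; the diagonal
    entry at y depends on the same rates of *every* absent event j with
    coefficient -1 (resp. -y_i).
    """
    bits_matrix, rows, cols, events = _subspace_structure(n, active)
    dR = np.zeros((n, n))
    bits_f = bits_matrix.astype(float)
    # Off-diagonal transition entries (events inside the active set):
    # dR[j, j] += dQ[a, b];  dR[i, j] += y_i(a) * dQ[a, b].
    d_trans = dQ[rows, cols]
    np.add.at(dR, (events, events), d_trans)
    for j in set(events.tolist()):
        mask = events == j
        dR[:, j] += d_trans[mask] @ bits_f[rows[mask]]
    # Diagonal (exit-rate) entries: every absent event of every sub-state.
    d_diag = np.diag(dQ)
    absent = 1.0 - bits_f  # (m, n) indicator of absent events
    # dR[j, j] -= sum_a absent[a, j] * d_diag[a]
    diag_contrib = absent.T @ d_diag  # (n,)
    dR[np.arange(n), np.arange(n)] -= diag_contrib
    # dR[i, j] -= sum_a y_i(a) * absent[a, j] * d_diag[a]
    weighted = bits_f * d_diag[:, None]  # (m, n), column i = y_i * d_diag
    dR -= weighted.T @ absent
    return dR


def likelihood_grad_R(
    network: HazardNetwork,
    profile: Profile,
    t: float,
    k_max: int = DEFAULT_K_MAX,
) -> LikelihoodGradient:
    """Likelihood of one sample with exact partials w.r.t. R and t."""
    subsys = build_subspace_generator(network, profile, k_max=k_max)
    dQ = expm_entry_derivative(subsys, t, k_max=k_max)
    value = float(expm(t * subsys.generator)[0, -1])
    dR = _contract_structural(dQ, network.n, profile.active)
    dt = likelihood_grad_t(subsys, t)
    return LikelihoodGradient(value=value, dR=dR, dt=dt)
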