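"""Structure-recovery scoring of an inferred hazard network against truth.

Only directed inter-event (off-diagonal) edges are scored; spontaneous
rates are excluded because competing structure-learning methods do not
estimate them comparably.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RecoveryMetrics", "compare_graphs", "aggregate_metrics"]


@dataclass(frozen=True)
class RecoveryMetrics:
    """Directed-edge recovery counts and the derived scores.

    ``precision = tp/(tp+fp)``, ``recall = tp/(tp+fn)`` and
    ``fscore = 2tp/(2tp+fp+fn)`` (harmonic mean of the two); each is defined
    as 0 when its denominator vanishes, with ``degenerate`` flagging that
    convention was used.
    """

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    fscore: float
    degenerate: bool = False


def compare_graphs(
    true_adjacency, inferred_adjacency, directed: bool = True
) -> RecoveryMetrics:
    """Edge-wise comparison of two binary adjacency matrices.

    With ``directed=False`` both graphs are symmetrized first (skeleton
    comparison); the default scores direction-sensitive edges.
    """
    A = np.asarray(true_adjacency)
    B = np.asarray(inferred_adjacency)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency shapes disagree: {A.shape} vs {B.shape}")
    if not (np.isin(A, (0, 1)).all() and np.isin(B, (0, 1)).all()):
        raise ValueError("adjacency matrices must be binary")
    if np.any(np.diag(A)) or np.any(np.diag(B)):
        raise ValueError("adjacency diagonals must be zero")
    A = A.astype(bool)
    B = B.astype(bool)
    if not directed:
        A = A | A.T
        B = B | B.T
    tp = int((A & B).sum())
    fp = int((~A & B).sum())
    fn = int((A & ~B).sum())
    degenerate = (tp + fp == 0) or (tp + fn == 0) or (2 * tp + fp + fn == 0)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    fscore = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return RecoveryMetrics(tp, fp, fn, precision, recall, fscore, degenerate)


def aggregate_metrics(metrics: list[RecoveryMetrics]) -> pd.DataFrame:
    """Per-replicate rows plus a mean +/- sd summary row (ddof=1)."""
    rows = pd.DataFrame(
        [
            {
                "tp": m.tp,
                "fp": m.fp,
                "fn": m.fn,
                "precision": m.precision,
                "recall": m.recall,
                "fscore": m.fscore,
            }
            for m in metrics
        ]
    )
    rows.index.name = "replicate"
    summary = rows[["precision", "recall", "fscore"]].agg(["mean", "std"])
    return rows, summary
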