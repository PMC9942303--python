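"""Rank-pair discriminant scores for two-class feature profiles.

The discriminant score of an ordered feature pair ``(i, j)`` is

    s_ij = | P(X_i < X_j | C = 1) - P(X_i < X_j | C = 2) |

with both class-conditional probabilities estimated by the sample
proportions of profiles in which feature ``i`` lies strictly below
feature ``j``.  A pair scores 1 when the within-profile ordering
perfectly separates the two classes and 0 when the ordering is equally
frequent in both.  Because only within-profile orderings enter, every
score is invariant to strictly increasing transformations applied to a
sample's profile, which makes the statistic robust to monotone
normalization of abundance data.

Ties ``X_i == X_j`` count as *not* satisfying ``X_i < X_j`` (the strict
indicator); with continuous abundances ties are rare.

Equal top scores are broken by a secondary rank score: the absolute
between-class difference of the mean within-profile rank difference of
the two features (average ranks for ties), followed by lexicographic
order on the index pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ScoredPair",
    "pair_score",
    "all_pair_scores",
    "secondary_rank_score",
    "rank_matrix",
    "score_table",
]

#: column block size for the pairwise ordering computation; bounds the
#: temporary boolean tensor at N * p * _BLOCK entries.
_BLOCK = 128


@dataclass(frozen=True)
class ScoredPair:
    """A feature pair with its class-conditional ordering proportions.

    ``p1`` (``p2``) is the proportion of class-1 (class-2) training
    samples with ``X_i < X_j``; ``score = |p1 - p2|``; ``rank_score`` is
    the secondary tie-break statistic.
    """

    i: int
    j: int
    p1: float
    p2: float
    score: float
    rank_score: float


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"feature matrix must be 2-D, got shape {X.shape}")
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError(
            f"need at least 2 samples and 2 features, got shape {X.shape}"
        )
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    return X


def _class_masks(y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (mask of class 1, mask of class 2, sorted class values)."""
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(
            f"labels must contain exactly two classes, found {classes.tolist()}"
        )
    m1 = y == classes[0]
    m2 = y == classes[1]
    if not (m1.any() and m2.any()):  # pragma: no cover - unique guarantees this
        raise ValueError("each class needs at least one sample")
    return m1, m2, classes


def pair_score(X, y, i: int, j: int) -> ScoredPair:
    """Score a single feature pair ``(i, j)`` against binary labels.

    Classes are the two sorted unique label values; "class 1" is the
    smaller one.  Raises if ``i == j`` or a class is absent.
    """
    X = _as_matrix(X)
    if i == j:
        raise ValueError(f"pair indices must differ, got ({i}, {j})")
    m1, m2, _ = _class_masks(y)
    less = X[:, i] < X[:, j]
    p1 = float(less[m1].mean())
    p2 = float(less[m2].mean())
    return ScoredPair(
        i=i,
        j=j,
        p1=p1,
        p2=p2,
        score=abs(p1 - p2),
        rank_score=secondary_rank_score(X, y, i, j),
    )


def rank_matrix(X) -> np.ndarray:
    """Within-sample ranks of each profile (average rank for ties).

    Row sums are constant at ``p (p + 1) / 2``.
    """
    return rankdata(_as_matrix(X), axis=1)


def secondary_rank_score(X, y, i: int, j: int) -> float:
    """Tie-break statistic: |mean_C1(R_i - R_j) - mean_C2(R_i - R_j)|.

    ``R`` are within-sample ranks, so the statistic shares the monotone
    invariance of the primary score.
    """
    X = _as_matrix(X)
    if i == j:
        raise ValueError(f"pair indices must differ, got ({i}, {j})")
    m1, m2, _ = _class_masks(y)
    R = rankdata(X, axis=1)
    d = R[:, i] - R[:, j]
    return float(abs(d[m1].mean() - d[m2].mean()))


def _ordering_proportions(Xc: np.ndarray) -> np.ndarray:
    """p x p matrix of proportions of rows with X[:, i] < X[:, j]."""
    n, p = Xc.shape
    P = np.empty((p, p))
    for start in range(0, p, _BLOCK):
        sl = slice(start, min(start + _BLOCK, p))
        P[:, sl] = (Xc[:, :, None] < Xc[:, None, sl]).mean(axis=0)
    return P


def all_pair_scores(X, y) -> list[ScoredPair]:
    """Score every unordered feature pair; deterministic ordering.

    Returns ``p (p - 1) / 2`` entries sorted by descending score, then
    descending rank score, then ascending ``(i, j)``.
    """
    X = _as_matrix(X)
    m1, m2, _ = _class_masks(y)
    P1 = _ordering_proportions(X[m1])
    P2 = _ordering_proportions(X[m2])

    R = rankdata(X, axis=1)
    delta = R[m1].mean(axis=0) - R[m2].mean(axis=0)

    p = X.shape[1]
    iu, ju = np.triu_indices(p, k=1)
    p1 = P1[iu, ju]
    p2 = P2[iu, ju]
    score = np.abs(p1 - p2)
    rank_score = np.abs(delta[iu] - delta[ju])

    order = np.lexsort((ju, iu, -rank_score, -score))
    return [
        ScoredPair(
            i=int(iu[k]),
            j=int(ju[k]),
            p1=float(p1[k]),
            p2=float(p2[k]),
            score=float(score[k]),
            rank_score=float(rank_score[k]),
        )
        for k in order
    ]


def score_table(X, y, feature_ids=None) -> pd.DataFrame:
    """All pair scores as a tidy table (one row per unordered pair)."""
    X_arr = _as_matrix(X)
    if feature_ids is None:
        if isinstance(X, pd.DataFrame):
            feature_ids = list(X.columns)
        else:
            feature_ids = [f"F{k + 1}" for k in range(X_arr.shape[1])]
    pairs = all_pair_scores(X_arr, y)
    return pd.DataFrame(
        {
            "feature_i": [feature_ids[sp.i] for sp in pairs],
            "feature_j": [feature_ids[sp.j] for sp in pairs],
            "p1": [sp.p1 for sp in pairs],
            "p2": [sp.p2 for sp in pairs],
            "score": [sp.score for sp in pairs],
            "rank_score": [sp.rank_score for sp in pairs],
        }
    )
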