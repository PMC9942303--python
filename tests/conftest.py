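"""Shared fixtures and independent brute-force oracles.

The oracle functions recompute pair scores, rank scores and the
ensemble criterion with explicit double loops, independent of the
package's vectorized implementations.
"""

import numpy as np
import pytest

from catsp import simulate_study1


def brute_pair_counts(X, y, i, j):
    """(p1, p2) by explicit counting of strict orderings per class."""
    classes = sorted(set(np.asarray(y).tolist()))
    assert len(classes) == 2
    props = []
    for c in classes:
        rows = [k for k in range(len(y)) if y[k] == c]
        count = sum(1 for k in rows if X[k][i] < X[k][j])
        props.append(count / len(rows))
    return props[0], props[1]


def brute_pair_score(X, y, i, j):
    p1, p2 = brute_pair_counts(X, y, i, j)
    return abs(p1 - p2)


def brute_rank_score(X, y, i, j):
    """Between-class difference of mean within-profile rank differences."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    ranks = np.empty_like(X)
    for k in range(n):
        row = X[k]
        for m in range(p):
            ranks[k, m] = (
                sum(1 for v in row if v < row[m])
                + 1
                + 0.5 * (sum(1 for v in row if v == row[m]) - 1)
            )
    classes = sorted(set(np.asarray(y).tolist()))
    means = []
    for c in classes:
        rows = [k for k in range(n) if y[k] == c]
        means.append(sum(ranks[k, i] - ranks[k, j] for k in rows) / len(rows))
    return abs(means[0] - means[1])


def brute_tau(pairs, X, y):
    """Eq.-style criterion by explicit loops; pairs are (i, j) tuples."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    numerator = sum(brute_pair_score(X, y, i, j) for i, j in pairs)
    votes = [
        sum(1 for (i, j) in pairs if X[k, i] < X[k, j]) for k in range(len(y))
    ]
    total_var = 0.0
    for c in sorted(set(y.tolist())):
        v = [votes[k] for k in range(len(y)) if y[k] == c]
        if len(v) > 1:
            mean = sum(v) / len(v)
            total_var += sum((x - mean) ** 2 for x in v) / (len(v) - 1)
    if total_var == 0.0:
        return float("inf")
    return numerator / total_var**0.5


@pytest.fixture(scope="session")
def study1():
    """One fixed cohort from the confounded-pair generator."""
    return simulate_study1(n_samples=200, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
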