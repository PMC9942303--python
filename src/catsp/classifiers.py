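"""Top-scoring pair (TSP) and K-TSP classifiers.

``TSPClassifier`` fits the single feature pair whose within-profile
ordering best discriminates two classes; ``KTSPClassifier`` fits an
ensemble of feature-disjoint pairs that classify by majority vote, with
the ensemble size chosen by a variance-normalized criterion.

Both are parameter-free rank-based rules: training estimates the two
class-conditional ordering proportions of each candidate pair and
prediction only inspects the ordering of the selected features in a
test profile.  Both estimators follow the scikit-learn API (``fit`` /
``predict`` / ``get_params``) and accept numpy arrays or pandas
DataFrames; models fit on DataFrames predict by column *name*, so
re-exported tables with shuffled columns classify identically.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .scoring import ScoredPair, all_pair_scores

__all__ = [
    "TSPClassifier",
    "KTSPClassifier",
    "select_disjoint_pairs",
    "ktsp_tau",
    "fit_tsp",
    "fit_ktsp",
]

logger = logging.getLogger(__name__)

DEFAULT_K_GRID = tuple(range(2, 11))


def select_disjoint_pairs(scores: list[ScoredPair], k_max: int) -> list[ScoredPair]:
    """Greedily pick up to ``k_max`` feature-disjoint pairs.

    Walks the deterministically sorted score list and keeps each pair
    that shares no feature with an already kept one; the first kept pair
    is therefore the TSP top pair.  Returns fewer than ``k_max`` pairs
    (with a warning) when the features are exhausted.
    """
    if k_max < 1:
        raise ValueError(f"k_max must be >= 1, got {k_max}")
    selected: list[ScoredPair] = []
    used: set[int] = set()
    for sp in scores:
        if sp.i in used or sp.j in used:
            continue
        selected.append(sp)
        used.update((sp.i, sp.j))
        if len(selected) == k_max:
            break
    if len(selected) < k_max:
        warnings.warn(
            f"only {len(selected)} disjoint pairs available, requested {k_max}",
            stacklevel=2,
        )
    return selected


def ktsp_tau(pairs: list[ScoredPair], X, y) -> float:
    """Variance-normalized ensemble criterion for a set of disjoint pairs.

    Numerator: the sum of the pairs' discriminant scores.  Denominator:
    the square root of the summed within-class sample variances
    (denominator ``N_c - 1``) of the per-sample count of orderings
    ``X_i < X_j`` across the pairs.  Returns ``inf`` when both
    within-class variances vanish (e.g. a single perfectly separating
    pair), which is treated as maximal.
    """
    if not pairs:
        raise ValueError("need at least one pair")
    used = [f for sp in pairs for f in (sp.i, sp.j)]
    if len(set(used)) != len(used):
        raise ValueError("pairs must be feature-disjoint")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    votes = np.zeros(X.shape[0])
    for sp in pairs:
        votes += X[:, sp.i] < X[:, sp.j]
    total = 0.0
    for c in classes:
        v = votes[y == c]
        total += float(v.var(ddof=1)) if v.size > 1 else 0.0
    numerator = sum(sp.score for sp in pairs)
    if total == 0.0:
        warnings.warn(
            "zero within-class variance of the vote count; tau is infinite",
            stacklevel=2,
        )
        return float("inf")
    return float(numerator / np.sqrt(total))


class _PairedRankClassifier(ClassifierMixin, BaseEstimator):
    """Shared fitting plumbing for the TSP-family classifiers."""

    def _validate_fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X_arr = X.to_numpy(dtype=float)
        else:
            X_arr = np.asarray(X, dtype=float)
        if X_arr.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        y = np.asarray(y).ravel()
        if y.shape[0] != X_arr.shape[0]:
            raise ValueError(
                f"X has {X_arr.shape[0]} samples but y has {y.shape[0]}"
            )
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(
                f"exactly two classes required, found {self.classes_.tolist()}"
            )
        self.n_features_in_ = X_arr.shape[1]
        return X_arr, y

    def _validate_predict(self, X) -> np.ndarray:
        check_is_fitted(self, "classes_")
        if isinstance(X, pd.DataFrame):
            if hasattr(self, "feature_names_in_"):
                missing = [
                    f for f in self._required_features() if f not in X.columns
                ]
                if missing:
                    raise ValueError(
                        f"test data is missing model features: {missing}"
                    )
                return X.to_numpy(dtype=float), {
                    name: X.columns.get_loc(name) for name in X.columns
                }
            return X.to_numpy(dtype=float), None
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < self.n_features_in_:
            raise ValueError(
                f"expected at least {self.n_features_in_} feature columns"
            )
        return X, None

    def _required_features(self):  # pragma: no cover - overridden
        raise NotImplementedError

    def _column(self, colmap, index: int) -> int:
        """Map a training feature index to a test column index."""
        if colmap is None:
            return index
        return colmap[self.feature_names_in_[index]]


def _orientation(sp: ScoredPair, classes: np.ndarray) -> tuple:
    """(class when X_i < X_j, class when X_i >= X_j) for one pair.

    If ``p1 < p2`` on training data, observing the ordering predicts
    class 2; otherwise (including the exact tie ``p1 == p2``) it
    predicts class 1.
    """
    if sp.p1 < sp.p2:
        return classes[1], classes[0]
    return classes[0], classes[1]


class TSPClassifier(_PairedRankClassifier):
    """Single top-scoring pair classifier.

    Fitting scans all ``p (p - 1) / 2`` feature pairs and keeps the one
    with the maximal discriminant score (ties broken by the secondary
    rank score, then lexicographically).  Prediction observes the
    ordering of the two selected features in a test profile; a tie
    ``X_i == X_j`` counts as ``X_i >= X_j``.

    Attributes
    ----------
    pair_ : ScoredPair
        The selected pair with its training proportions.
    feature_pair_ : tuple
        Identifiers of the selected features (column names when fit on
        a DataFrame, integer indices otherwise).
    class_if_less_, class_if_geq_ : label
        Predicted class for each observed ordering.
    """

    def fit(self, X, y):
        X_arr, y = self._validate_fit(X, y)
        scored = all_pair_scores(X_arr, y)
        self.pair_ = scored[0]
        if self.pair_.score == 0.0:
            logger.warning("all pair scores are zero; fitted rule is uninformative")
        self.class_if_less_, self.class_if_geq_ = _orientation(
            self.pair_, self.classes_
        )
        if hasattr(self, "feature_names_in_"):
            self.feature_pair_ = (
                self.feature_names_in_[self.pair_.i],
                self.feature_names_in_[self.pair_.j],
            )
        else:
            self.feature_pair_ = (self.pair_.i, self.pair_.j)
        self.score_ = self.pair_.score
        return self

    def _required_features(self):
        return list(self.feature_pair_)

    def predict(self, X):
        X_arr, colmap = self._validate_predict(X)
        ci = self._column(colmap, self.pair_.i)
        cj = self._column(colmap, self.pair_.j)
        less = X_arr[:, ci] < X_arr[:, cj]
        return np.where(less, self.class_if_less_, self.class_if_geq_)

    def to_dict(self) -> dict:
        check_is_fitted(self, "pair_")
        from . import __version__

        return {
            "type": "tsp",
            "version": __version__,
            "classes": [_jsonable(c) for c in self.classes_],
            "pair": _pair_record(self.pair_, self.feature_pair_),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TSPClassifier":
        if d.get("type") != "tsp":
            raise ValueError(f"not a TSP model record: {d.get('type')!r}")
        model = cls()
        model.classes_ = np.asarray(d["classes"])
        rec = d["pair"]
        model.feature_pair_ = tuple(rec["features"])
        if all(isinstance(f, int) for f in rec["features"]):
            # array-fitted model: stored values are column indices
            fi, fj = rec["features"]
            model.pair_ = _record_pair(rec, fi, fj)
            model.n_features_in_ = max(fi, fj) + 1
        else:
            model.feature_names_in_ = np.asarray(rec["features"], dtype=object)
            model.pair_ = _record_pair(rec, 0, 1)
            model.n_features_in_ = 2
        model.score_ = model.pair_.score
        model.class_if_less_, model.class_if_geq_ = _orientation(
            model.pair_, model.classes_
        )
        return model


class KTSPClassifier(_PairedRankClassifier):
    """K top-scoring disjoint pairs with majority voting.

    Pairs are selected greedily in score order under the constraint
    that no feature repeats, producing nested candidate sets; the
    ensemble size ``k*`` is the grid value maximizing the
    variance-normalized criterion (:func:`ktsp_tau`), ties toward
    smaller ``k``.  Each pair votes per its training orientation; the
    majority class wins, and an even-split vote is decided by the
    top-scoring pair.

    Parameters
    ----------
    k_grid : iterable of int, optional
        Candidate ensemble sizes; default 2..10.
    """

    def __init__(self, k_grid=None):
        self.k_grid = k_grid

    def _resolved_grid(self) -> tuple[int, ...]:
        grid = DEFAULT_K_GRID if self.k_grid is None else tuple(self.k_grid)
        grid = tuple(sorted(set(int(k) for k in grid)))
        if not grid or grid[0] < 1:
            raise ValueError(f"k_grid must contain positive integers, got {grid}")
        return grid

    def fit(self, X, y):
        X_arr, y = self._validate_fit(X, y)
        grid = self._resolved_grid()
        if X_arr.shape[1] < 2 * grid[0]:
            raise ValueError(
                f"{X_arr.shape[1]} features cannot support k = {grid[0]} "
                "disjoint pairs"
            )
        scored = all_pair_scores(X_arr, y)
        candidates = select_disjoint_pairs(scored, grid[-1])
        self.tau_by_k_ = {}
        for k in grid:
            if k <= len(candidates):
                self.tau_by_k_[k] = ktsp_tau(candidates[:k], X_arr, y)
        k_star, best = None, -np.inf
        for k in sorted(self.tau_by_k_):
            if self.tau_by_k_[k] > best:
                k_star, best = k, self.tau_by_k_[k]
        self.k_star_ = k_star
        self.pairs_ = candidates[:k_star]
        self.orientations_ = [_orientation(sp, self.classes_) for sp in self.pairs_]
        if hasattr(self, "feature_names_in_"):
            self.feature_pairs_ = [
                (self.feature_names_in_[sp.i], self.feature_names_in_[sp.j])
                for sp in self.pairs_
            ]
        else:
            self.feature_pairs_ = [(sp.i, sp.j) for sp in self.pairs_]
        return self

    def _required_features(self):
        return [f for pair in self.feature_pairs_ for f in pair]

    def predict(self, X):
        X_arr, colmap = self._validate_predict(X)
        n = X_arr.shape[0]
        votes_c2 = np.zeros(n, dtype=int)
        first_vote = None
        for sp, (cls_less, cls_geq) in zip(self.pairs_, self.orientations_):
            less = (
                X_arr[:, self._column(colmap, sp.i)]
                < X_arr[:, self._column(colmap, sp.j)]
            )
            vote = np.where(less, cls_less, cls_geq)
            votes_c2 += vote == self.classes_[1]
            if first_vote is None:
                first_vote = vote
        k = len(self.pairs_)
        pred = np.where(votes_c2 * 2 > k, self.classes_[1], self.classes_[0])
        if k % 2 == 0:
            tie = votes_c2 * 2 == k
            pred[tie] = first_vote[tie]
        return pred

    def to_dict(self) -> dict:
        check_is_fitted(self, "pairs_")
        from . import __version__

        return {
            "type": "ktsp",
            "version": __version__,
            "classes": [_jsonable(c) for c in self.classes_],
            "k_star": self.k_star_,
            "tau_by_k": {
                str(k): (None if np.isinf(v) else float(v))
                for k, v in self.tau_by_k_.items()
            },
            "pairs": [
                _pair_record(sp, names)
                for sp, names in zip(self.pairs_, self.feature_pairs_)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KTSPClassifier":
        if d.get("type") != "ktsp":
            raise ValueError(f"not a K-TSP model record: {d.get('type')!r}")
        model = cls()
        model.classes_ = np.asarray(d["classes"])
        names: list = []
        pairs: list[ScoredPair] = []
        feature_pairs = []
        all_int = all(
            isinstance(f, int) for rec in d["pairs"] for f in rec["features"]
        )
        for rec in d["pairs"]:
            fi, fj = rec["features"]
            for f in (fi, fj):
                if f in names:
                    raise ValueError(f"duplicate feature {f!r} across stored pairs")
                names.append(f)
            if all_int:  # array-fitted model: stored values are column indices
                pairs.append(_record_pair(rec, fi, fj))
            else:
                pairs.append(_record_pair(rec, names.index(fi), names.index(fj)))
            feature_pairs.append((fi, fj))
        model.pairs_ = pairs
        model.feature_pairs_ = feature_pairs
        if all_int:
            model.n_features_in_ = max(names) + 1
        else:
            model.feature_names_in_ = np.asarray(names, dtype=object)
            model.n_features_in_ = len(names)
        model.k_star_ = d["k_star"]
        model.tau_by_k_ = {
            int(k): (float("inf") if v is None else v)
            for k, v in d["tau_by_k"].items()
        }
        model.orientations_ = [_orientation(sp, model.classes_) for sp in pairs]
        return model


def _jsonable(value):
    return value.item() if isinstance(value, np.generic) else value


def _pair_record(sp: ScoredPair, features) -> dict:
    return {
        "features": [_jsonable(f) for f in features],
        "p1": sp.p1,
        "p2": sp.p2,
        "score": sp.score,
        "rank_score": sp.rank_score,
    }


def _record_pair(rec: dict, i: int, j: int) -> ScoredPair:
    return ScoredPair(i, j, rec["p1"], rec["p2"], rec["score"], rec["rank_score"])


def fit_tsp(X, y) -> TSPClassifier:
    """Fit a single top-scoring pair classifier."""
    return TSPClassifier().fit(X, y)


def fit_ktsp(X, y, k_grid=None) -> KTSPClassifier:
    """Fit a K-TSP classifier with ``k*`` selected over ``k_grid``."""
    return KTSPClassifier(k_grid=k_grid).fit(X, y)
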