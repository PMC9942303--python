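"""K-TSP: disjoint selection, the tau criterion, voting, k* search."""

import itertools

import numpy as np
import pytest

from catsp import (
    KTSPClassifier,
    ScoredPair,
    TSPClassifier,
    all_pair_scores,
    ktsp_tau,
    select_disjoint_pairs,
)

from conftest import brute_tau


def _sp(i, j, score):
    return ScoredPair(i=i, j=j, p1=score, p2=0.0, score=score, rank_score=0.0)


class TestSelectDisjointPairs:
    def test_disjointness_forces_skipping(self):
        scores = [_sp(0, 1, 0.9), _sp(0, 2, 0.8), _sp(3, 4, 0.7)]
        picked = select_disjoint_pairs(scores, 2)
        assert [(sp.i, sp.j) for sp in picked] == [(0, 1), (3, 4)]

    def test_k_max_one_is_top_pair(self, rng):
        X = rng.normal(size=(12, 5))
        y = [1, 2] * 6
        scores = all_pair_scores(X, y)
        assert select_disjoint_pairs(scores, 1) == [scores[0]]

    def test_exhaustion_warns_and_returns_fewer(self):
        with pytest.warns(UserWarning, match="disjoint pairs available"):
            picked = select_disjoint_pairs([_sp(0, 1, 0.5), _sp(0, 2, 0.4)], 3)
        assert len(picked) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_greedy_near_exhaustive_on_small_instances(self, seed):
        """Greedy total score matches the exhaustive best 2-pair disjoint
        set on most small instances; it never exceeds it (the rare gap is
        the known greedy/matching discrepancy)."""
        rng = np.random.default_rng(seed)
        n, p = 10, 6
        X = rng.normal(size=(n, p))
        y = rng.integers(0, 2, size=n)
        y[:2] = [0, 1]
        scores = all_pair_scores(X, y)
        greedy = select_disjoint_pairs(scores, 2)
        greedy_total = sum(sp.score for sp in greedy)
        best = max(
            (
                a.score + b.score
                for a, b in itertools.combinations(scores, 2)
                if len({a.i, a.j, b.i, b.j}) == 4
            ),
        )
        assert greedy_total <= best + 1e-12
        if greedy_total < best - 1e-12:
            pytest.xfail("known greedy gap on this instance")


class TestTau:
    def test_hand_computed_toy_table(self):
        # 6 samples, 2 disjoint pairs; vote counts per sample are
        # hand-checkable: class 1 -> (2, 2, 1), class 2 -> (0, 1, 0)
        X = np.array(
            [
                [0, 1, 0, 1],
                [0, 1, 0, 1],
                [0, 1, 1, 0],
                [1, 0, 1, 0],
                [1, 0, 0, 1],
                [1, 0, 1, 0],
            ],
            dtype=float,
        )
        y = np.array([1, 1, 1, 2, 2, 2])
        pairs = [p for p in all_pair_scores(X, y) if (p.i, p.j) in ((0, 1), (2, 3))]
        tau = ktsp_tau(pairs, X, y)
        # scores: (0,1) -> |1 - 0| = 1; (2,3) -> |2/3 - 1/3| = 1/3
        # variances: class 1 votes (2,2,1) -> 1/3; class 2 (0,1,0) -> 1/3
        expected = (1 + 1 / 3) / np.sqrt(1 / 3 + 1 / 3)
        assert tau == pytest.approx(expected)
        assert tau == pytest.approx(brute_tau([(0, 1), (2, 3)], X, y))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_random(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 6))
        y = rng.integers(0, 2, size=12)
        y[:2] = [0, 1]
        pairs = select_disjoint_pairs(all_pair_scores(X, y), 3)
        idx = [(sp.i, sp.j) for sp in pairs]
        assert ktsp_tau(pairs, X, y) == pytest.approx(brute_tau(idx, X, y))

    def test_numerator_equals_sum_of_scores(self, rng):
        X = rng.normal(size=(16, 6))
        y = [1, 2] * 8
        pairs = select_disjoint_pairs(all_pair_scores(X, y), 3)
        votes = np.zeros(16)
        for sp in pairs:
            votes += X[:, sp.i] < X[:, sp.j]
        y_arr = np.asarray(y)
        den = np.sqrt(
            votes[y_arr == 1].var(ddof=1) + votes[y_arr == 2].var(ddof=1)
        )
        assert ktsp_tau(pairs, X, y) * den == pytest.approx(
            sum(sp.score for sp in pairs)
        )

    def test_perfect_pair_gives_infinite_sentinel(self):
        X = np.array([[0, 1], [0, 2], [3, 1], [5, 2]], dtype=float)
        y = [1, 1, 2, 2]
        pairs = all_pair_scores(X, y)
        with pytest.warns(UserWarning, match="zero within-class variance"):
            assert ktsp_tau(pairs[:1], X, y) == np.inf

    def test_scaling_invariance(self, rng):
        X = rng.normal(size=(14, 4))
        y = [1, 2] * 7
        pairs = select_disjoint_pairs(all_pair_scores(X, y), 2)
        assert ktsp_tau(pairs, X, y) == ktsp_tau(pairs, X * 7.3, y)

    def test_overlapping_pairs_rejected(self, rng):
        X = rng.normal(size=(8, 3))
        y = [1, 2] * 4
        sps = all_pair_scores(X, y)
        with pytest.raises(ValueError, match="disjoint"):
            ktsp_tau(sps[:2], X, y)  # 3 features -> any 2 pairs overlap


def _planted(rng, n=60, p=10, shift=3.0):
    """Two planted order-reversal pairs among features 0-3; rest noise."""
    X = rng.normal(size=(n, p))
    y = np.where(np.arange(n) < n // 2, 1, 2)
    sign = np.where(y == 1, 1.0, -1.0)
    X[:, 0] += shift * sign
    X[:, 1] -= shift * sign
    X[:, 2] += shift * sign
    X[:, 3] -= shift * sign
    return X, y


class TestFitKTSP:
    def test_fitted_pairs_are_disjoint(self, rng):
        X, y = _planted(rng)
        model = KTSPClassifier().fit(X, y)
        used = [f for pair in model.feature_pairs_ for f in pair]
        assert len(used) == len(set(used))

    def test_k_star_recovers_planted_pair_count(self):
        hits = 0
        for seed in range(10):
            X, y = _planted(np.random.default_rng(seed))
            model = KTSPClassifier().fit(X, y)
            if model.k_star_ == 2 and {0, 1, 2, 3} == set(
                f for pair in model.feature_pairs_ for f in pair
            ):
                hits += 1
        assert hits >= 7

    def test_k_grid_one_reduces_to_tsp(self, rng):
        X, y = _planted(rng)
        ktsp = KTSPClassifier(k_grid=[1]).fit(X, y)
        tsp = TSPClassifier().fit(X, y)
        assert ktsp.pairs_ == [tsp.pair_]
        X_new = np.random.default_rng(1).normal(size=(20, X.shape[1]))
        assert np.array_equal(ktsp.predict(X_new), tsp.predict(X_new))

    def test_tau_ties_break_toward_smaller_k(self):
        X = np.array([[0, 1, 0, 1], [0, 1, 0, 1], [1, 0, 1, 0], [1, 0, 1, 0]],
                     dtype=float)
        y = [1, 1, 2, 2]
        with pytest.warns(UserWarning):
            model = KTSPClassifier(k_grid=[1, 2]).fit(X, y)
        # both k give the infinite sentinel; the smaller k wins
        assert model.k_star_ == 1

    def test_too_few_features_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="disjoint pairs"):
            KTSPClassifier(k_grid=[2]).fit(X, [1, 2] * 5)

    def test_monotone_transform_invariance_of_fit(self, rng):
        X, y = _planted(rng)
        m1 = KTSPClassifier().fit(X, y)
        scale = rng.uniform(0.5, 2.0, size=(X.shape[0], 1))
        m2 = KTSPClassifier().fit(np.exp(X) * scale, y)
        assert m1.feature_pairs_ == m2.feature_pairs_
        assert m1.k_star_ == m2.k_star_

    def test_stored_tau_matches_recomputation(self, rng):
        X, y = _planted(rng)
        model = KTSPClassifier().fit(X, y)
        assert model.tau_by_k_[model.k_star_] == pytest.approx(
            ktsp_tau(model.pairs_, X, y)
        )


class TestPredictKTSP:
    def _model_from_pairs(self, records):
        return KTSPClassifier.from_dict(
            {"type": "ktsp", "classes": [1, 2], "k_star": len(records),
             "tau_by_k": {str(len(records)): 1.0}, "pairs": records}
        )

    @staticmethod
    def _rec(fi, fj, p1, p2, score):
        return {"features": [fi, fj], "p1": p1, "p2": p2, "score": score,
                "rank_score": 0.0}

    def test_strict_majority(self):
        # three pairs, all vote class 2 when ordering observed
        model = self._model_from_pairs(
            [self._rec(f"a{k}", f"b{k}", 0.0, 1.0, 1.0) for k in range(3)]
        )
        import pandas as pd

        cols = ["a0", "b0", "a1", "b1", "a2", "b2"]
        # pairs vote (2, 2, 1): first two orderings observed, third not
        X = pd.DataFrame([[0, 1, 0, 1, 2, 1]], columns=cols, dtype=float)
        assert model.predict(X)[0] == 2

    def test_even_tie_decided_by_top_pair(self):
        model = self._model_from_pairs(
            [self._rec("a0", "b0", 0.0, 1.0, 1.0),
             self._rec("a1", "b1", 0.0, 1.0, 0.5)]
        )
        import pandas as pd

        # votes (2, 1): the higher-scoring first pair decides
        X = pd.DataFrame([[0, 1, 2, 1]], columns=["a0", "b0", "a1", "b1"],
                         dtype=float)
        assert model.predict(X)[0] == 2
        # votes (1, 2): still the first pair
        X2 = pd.DataFrame([[2, 1, 0, 1]], columns=["a0", "b0", "a1", "b1"],
                          dtype=float)
        assert model.predict(X2)[0] == 1
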