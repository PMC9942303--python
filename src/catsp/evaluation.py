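"""Repeated stratified cross-validation and the six accuracy measures.

The evaluation protocol is 100 iterations of 5-fold cross-validation:
each iteration re-randomizes the fold partition, every fold serves as
the test set once, and the across-fold averages of the measures form
one cross-validated estimate per iteration.  The six measures are
overall accuracy, sensitivity, specificity, balanced accuracy
(mean of sensitivity and specificity), positive predictive value and
negative predictive value, all derived from the fold's confusion
matrix with a declared positive class.

A measure whose denominator is empty (e.g. PPV when a fold produces no
positive predictions) is undefined: it is reported as NaN, excluded
from that measure's across-fold average, and the number of such folds
is counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone, is_classifier
from sklearn.model_selection import KFold, StratifiedKFold

from .classifiers import KTSPClassifier, TSPClassifier
from .residualize import CovariateResidualizer

__all__ = ["MetricsReport", "CVResult", "confusion_metrics", "repeated_cv"]

METRIC_NAMES = (
    "overall_accuracy",
    "sensitivity",
    "specificity",
    "balanced_accuracy",
    "ppv",
    "npv",
)


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and the six accuracy measures for one test set."""

    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: object = 1

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    @property
    def overall_accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.tp + self.fp + self.tn + self.fn)

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0

    @property
    def ppv(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion_metrics(y_true, y_pred, positive_class=None) -> MetricsReport:
    """Build a :class:`MetricsReport` from aligned truth/prediction vectors.

    ``positive_class`` defaults to the larger of the two sorted labels
    observed in ``y_true`` (e.g. 1 for 0/1 coding, 2 for 1/2 coding).
    """
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.shape[0] != y_pred.shape[0]:
        raise ValueError(
            f"length mismatch: {y_true.shape[0]} truths vs {y_pred.shape[0]} "
            "predictions"
        )
    if y_true.shape[0] == 0:
        raise ValueError("empty label vectors")
    if positive_class is None:
        positive_class = np.unique(y_true)[-1]
    t = y_true == positive_class
    p = y_pred == positive_class
    return MetricsReport(
        tp=int((t & p).sum()),
        fp=int((~t & p).sum()),
        tn=int((~t & ~p).sum()),
        fn=int((t & ~p).sum()),
        positive_class=positive_class,
    )


@dataclass
class CVResult:
    """Per-iteration fold-averaged accuracy measures.

    ``metrics`` has one row per iteration and one column per measure;
    undefined fold values were excluded from the averages and counted
    in ``undefined_folds``.  ``selected_pairs`` records, per iteration
    and fold, the feature pairs the fitted model used (empty for
    plug-in estimators without that notion).
    """

    metrics: pd.DataFrame
    undefined_folds: pd.DataFrame
    iterations: int
    folds: int
    seed: int | None
    selected_pairs: list = field(default_factory=list, repr=False)

    def summary(self) -> pd.DataFrame:
        """Median and IQR of each measure across iterations."""
        q = self.metrics.quantile([0.25, 0.5, 0.75])
        q.index = ["q25", "median", "q75"]
        return q.T


def _make_estimator(method):
    if method == "tsp":
        return TSPClassifier()
    if method == "ktsp":
        return KTSPClassifier()
    if is_classifier(method) or (hasattr(method, "fit") and hasattr(method, "predict")):
        return method
    raise ValueError(f"method must be 'tsp', 'ktsp' or an estimator, got {method!r}")


def _fitted_pairs(model) -> list[tuple]:
    if hasattr(model, "feature_pairs_"):
        return [tuple(p) for p in model.feature_pairs_]
    if hasattr(model, "feature_pair_"):
        return [tuple(model.feature_pair_)]
    return []


def repeated_cv(
    features,
    labels,
    covariates=None,
    method="tsp",
    residualize_mode: str = "none",
    iterations: int = 100,
    folds: int = 5,
    seed: int | None = None,
    stratified: bool = True,
    positive_class=None,
) -> CVResult:
    """Repeated k-fold cross-validation of a TSP-family (or plug-in) model.

    Parameters
    ----------
    features, labels : samples x features table and binary label vector.
    covariates : samples x covariates table; required unless
        ``residualize_mode == "none"``.
    method : ``"tsp"``, ``"ktsp"``, or any fit/predict estimator
        (cloned per fold).
    residualize_mode : ``"none"``, ``"per_fold"`` (fit the residualizer
        on the training folds only; the fold-safe default for adjusted
        runs) or ``"global"`` (residualize the whole table once before
        splitting, accepting train/test leakage for reproducibility of
        whole-dataset analyses).
    stratified : preserve class proportions within folds (default).

    Returns a :class:`CVResult`; identical seeds give identical results.
    """
    X = pd.DataFrame(features)
    y = np.asarray(labels).ravel()
    if residualize_mode not in ("none", "per_fold", "global"):
        raise ValueError(f"unknown residualize_mode {residualize_mode!r}")
    if residualize_mode != "none" and covariates is None:
        raise ValueError("residualize_mode requires a covariate table")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    Z = pd.DataFrame(covariates) if covariates is not None else None

    if residualize_mode == "global":
        X = CovariateResidualizer().fit_transform(X, Z)

    rng_seeds = np.random.SeedSequence(seed).generate_state(iterations)
    rows, undef_rows, all_pairs = [], [], []
    for it in range(iterations):
        splitter_cls = StratifiedKFold if stratified else KFold
        splitter = splitter_cls(
            n_splits=folds, shuffle=True, random_state=int(rng_seeds[it])
        )
        fold_metrics, iter_pairs = [], []
        for train_idx, test_idx in splitter.split(X, y):
            y_train, y_test = y[train_idx], y[test_idx]
            if np.unique(y_train).size < 2:
                raise ValueError(
                    "a training partition lost a class; use stratified folds"
                )
            X_train, X_test = X.iloc[train_idx], X.iloc[test_idx]
            if residualize_mode == "per_fold":
                res = CovariateResidualizer().fit(X_train, Z.iloc[train_idx])
                X_train = res.transform(X_train, Z.iloc[train_idx])
                X_test = res.transform(X_test, Z.iloc[test_idx])
            model = clone(_make_estimator(method))
            model.fit(X_train, y_train)
            report = confusion_metrics(
                y_test, model.predict(X_test), positive_class=positive_class
            )
            fold_metrics.append(report.to_dict())
            iter_pairs.append(_fitted_pairs(model))
        frame = pd.DataFrame(fold_metrics)
        rows.append(frame.mean(skipna=True))
        undef_rows.append(frame.isna().sum())
        all_pairs.append(iter_pairs)

    return CVResult(
        metrics=pd.DataFrame(rows).reset_index(drop=True),
        undefined_folds=pd.DataFrame(undef_rows).reset_index(drop=True),
        iterations=iterations,
        folds=folds,
        seed=seed,
        selected_pairs=all_pairs,
    )
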