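"""Covariate residualization of feature tables.

Clinical covariates that predict the outcome can also drive the
within-profile orderings that rank-pair classifiers select on, so the
selected pairs end up proxying known risk factors.  Residualizing
removes that channel: each feature is regressed on the covariates by
ordinary least squares (with intercept), and the residuals

    e_ik = X_ik - (b0_i + sum_m Z_km b_im)

replace the feature values before pair scoring.  On the fitting sample
OLS residuals are exactly orthogonal to (hence uncorrelated with) every
covariate column.  A fitted residualizer can be applied to held-out
samples with the stored coefficients, where no orthogonality guarantee
holds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["CovariateResidualizer", "residualize"]


def _to_matrix(table, what: str) -> tuple[np.ndarray, list | None]:
    if isinstance(table, pd.DataFrame):
        arr = table.to_numpy(dtype=float)
        names = list(table.columns)
    else:
        arr = np.asarray(table, dtype=float)
        names = None
    if arr.ndim != 2:
        raise ValueError(f"{what} must be a 2-D table, got shape {arr.shape}")
    if np.isnan(arr).any():
        raise ValueError(f"{what} contains missing values")
    return arr, names


def _check_alignment(X, Z):
    if isinstance(X, pd.DataFrame) and isinstance(Z, pd.DataFrame):
        if not X.index.equals(Z.index):
            if set(X.index) == set(Z.index):
                Z = Z.loc[X.index]
            else:
                raise ValueError(
                    "feature and covariate tables cover different samples"
                )
    return Z


class CovariateResidualizer(TransformerMixin, BaseEstimator):
    """Per-feature OLS regression on covariates; transform to residuals.

    ``fit(X, Z)`` solves, for each feature column of ``X``, the least
    squares regression on the design ``[1, Z]``; ``transform(X, Z)``
    subtracts the fitted values.  Binary covariates are expected
    0/1-coded and categorical covariates pre-encoded as indicators; a
    rank-deficient design raises with the offending columns named.

    Attributes
    ----------
    intercept_ : (p,) array
    coef_ : (p, q) array, one row per feature.
    covariate_names_in_, feature_names_in_ : column labels when the
        corresponding inputs were DataFrames.
    """

    def fit(self, X, Z):
        Z = _check_alignment(X, Z)
        X_arr, f_names = _to_matrix(X, "feature matrix")
        Z_arr, z_names = _to_matrix(Z, "covariate table")
        if X_arr.shape[0] != Z_arr.shape[0]:
            raise ValueError(
                f"{X_arr.shape[0]} feature rows vs {Z_arr.shape[0]} covariate rows"
            )
        design = np.column_stack([np.ones(Z_arr.shape[0]), Z_arr])
        self._check_rank(design, z_names)
        beta, *_ = np.linalg.lstsq(design, X_arr, rcond=None)
        self.intercept_ = beta[0]
        self.coef_ = beta[1:].T
        self.n_features_in_ = X_arr.shape[1]
        self.n_covariates_ = Z_arr.shape[1]
        if f_names is not None:
            self.feature_names_in_ = np.asarray(f_names, dtype=object)
        if z_names is not None:
            self.covariate_names_in_ = np.asarray(z_names, dtype=object)
        return self

    @staticmethod
    def _check_rank(design: np.ndarray, z_names) -> None:
        q, r, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(design.shape) * np.finfo(float).eps
        rank = int((diag > tol).sum())
        if rank < design.shape[1]:
            bad = sorted(piv[rank:])
            labels = ["intercept"] + (
                list(z_names)
                if z_names is not None
                else [f"Z{m + 1}" for m in range(design.shape[1] - 1)]
            )
            raise ValueError(
                "covariate design matrix is rank deficient; collinear "
                f"columns: {[labels[b] for b in bad]}"
            )

    def transform(self, X, Z):
        check_is_fitted(self, "coef_")
        Z = _check_alignment(X, Z)
        X_arr, f_names = _to_matrix(X, "feature matrix")
        Z_arr, z_names = _to_matrix(Z, "covariate table")
        if X_arr.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X_arr.shape[1]}"
            )
        if Z_arr.shape[1] != self.n_covariates_:
            raise ValueError(
                f"expected {self.n_covariates_} covariates, got {Z_arr.shape[1]}"
            )
        if (
            f_names is not None
            and hasattr(self, "feature_names_in_")
            and list(f_names) != list(self.feature_names_in_)
        ):
            raise ValueError("feature columns do not match the fitted model")
        if (
            z_names is not None
            and hasattr(self, "covariate_names_in_")
            and list(z_names) != list(self.covariate_names_in_)
        ):
            raise ValueError("covariate columns do not match the fitted model")
        fitted = self.intercept_ + Z_arr @ self.coef_.T
        resid = X_arr - fitted
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(resid, index=X.index, columns=X.columns)
        return resid

    def fit_transform(self, X, Z):
        return self.fit(X, Z).transform(X, Z)


def residualize(X, Z):
    """One-shot residualization of ``X`` on ``Z`` (fit and transform)."""
    return CovariateResidualizer().fit_transform(X, Z)
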