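"""Synthetic two-class data with a confounding binary covariate.

The generator emulates the situation the residualizing method targets:
a binary covariate ``Z`` (a "clinical risk factor") strongly predicts a
binary outcome ``Y``, one feature pair is driven by the covariate, and
a second pair is driven by the outcome directly.

Generative model (study 1; study 2 adds within-pair correlation):

* ``Z ~ Bernoulli(0.5)``; prior ``P(Y = 1 | Z) = |Z - 0.05|`` (0.95 for
  ``Z = 1``, 0.05 for ``Z = 0``).
* ``(X1, X2) | Z`` bivariate normal: means ``(0, 5)`` under ``Z = 0``
  and ``(5, 0)`` under ``Z = 1``, variance 2 each.  This pair carries
  outcome information only through ``Z``.
* A balanced latent component ``W ~ Bernoulli(0.5)``, independent of
  ``Z``, generates ``(X3, X4)``: means ``(0, 2.5)`` under ``W = 0`` and
  ``(2.5, 0)`` under ``W = 1``, variance 3 each.  This pair is
  independent of the covariate.
* The outcome is drawn from the Bayes posterior combining the
  ``(X3, X4)`` component densities with the ``Z``-dependent prior:
  ``Y ~ Bernoulli(P(Y = 1 | X3, X4, Z))`` with
  ``P(Y=1|X3,X4,Z) = f1 * pi / (f1 * pi + f0 * (1 - pi))``,
  ``pi = |Z - 0.05|``.

``Y`` is thus associated with ``(X1, X2)`` only via ``Z`` and with
``(X3, X4)`` directly; residualizing on ``Z`` should collapse the
former pair's discriminant score and roughly preserve the latter's.

Study 2 repeats the exercise over a grid of within-pair correlations
``rho`` from -1 to 1 (covariance ``2 rho`` for ``(X1, X2)`` and
``3 rho`` for ``(X3, X4)``); the grid endpoints are handled as
degenerate (perfectly correlated) normals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .residualize import residualize
from .scoring import pair_score

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "posterior_prob_y",
    "simulate_dataset",
    "simulate_study1",
    "simulate_study2",
    "default_rho_grid",
]


@dataclass
class SimulationConfig:
    """Parameters of the two-pair confounding generator."""

    n_samples: int = 200
    rho: float = 0.0
    prevalence_z: float = 0.5
    seed: int | None = None
    mean_x12_z0: tuple[float, float] = (0.0, 5.0)
    mean_x12_z1: tuple[float, float] = (5.0, 0.0)
    var_x12: float = 2.0
    mean_x34_c0: tuple[float, float] = (0.0, 2.5)
    mean_x34_c1: tuple[float, float] = (2.5, 0.0)
    var_x34: float = 3.0

    def __post_init__(self):
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [-1, 1], got {self.rho}")
        if not 0.0 < self.prevalence_z < 1.0:
            raise ValueError("prevalence_z must lie in (0, 1)")
        if self.var_x12 <= 0 or self.var_x34 <= 0:
            raise ValueError("variances must be positive")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")


@dataclass
class SimulatedDataset:
    """One simulated cohort: features, covariate, outcome, posterior."""

    features: pd.DataFrame
    covariates: pd.DataFrame
    labels: pd.Series
    posterior: np.ndarray
    latent_class: np.ndarray
    config: SimulationConfig = field(repr=False)


def _bvn_draw(rng, n: int, rho: float, var: float) -> np.ndarray:
    """n draws from a centered bivariate normal, exact at |rho| = 1."""
    L = np.sqrt(var) * np.array(
        [[1.0, 0.0], [rho, np.sqrt(max(0.0, 1.0 - rho * rho))]]
    )
    return rng.standard_normal((n, 2)) @ L.T


def _log_kernel(x3, x4, mean, var: float, rho: float) -> np.ndarray:
    u = (np.asarray(x3, dtype=float) - mean[0]) / np.sqrt(var)
    v = (np.asarray(x4, dtype=float) - mean[1]) / np.sqrt(var)
    q = (u * u - 2.0 * rho * u * v + v * v) / (1.0 - rho * rho)
    return -0.5 * q


def _log_kernel_degenerate(x3, x4, mean, var: float, sign: float) -> np.ndarray:
    """Log density along the support line x4 - m4 = sign (x3 - m3).

    Off-support points get -inf.
    """
    x3 = np.asarray(x3, dtype=float)
    x4 = np.asarray(x4, dtype=float)
    resid = (x4 - mean[1]) - sign * (x3 - mean[0])
    on_line = np.abs(resid) <= 1e-8 * np.sqrt(var)
    logk = -0.5 * (x3 - mean[0]) ** 2 / var
    return np.where(on_line, logk, -np.inf)


def posterior_prob_y(x3, x4, z, config: SimulationConfig) -> np.ndarray:
    """Bayes posterior ``P(Y = 1 | X3 = x3, X4 = x4, Z = z)``.

    The prior is ``pi = |z - 0.05|``; the likelihoods are the two
    ``(X3, X4)`` component densities (shared covariance, so
    normalization constants cancel).  At ``|rho| = 1`` the densities
    are degenerate along a line and the posterior is evaluated with the
    one-dimensional density on the support; a point off both supports
    returns the prior.
    """
    x3, x4, z = np.broadcast_arrays(
        np.asarray(x3, dtype=float),
        np.asarray(x4, dtype=float),
        np.asarray(z, dtype=float),
    )
    pi = np.abs(z - 0.05)
    if abs(config.rho) < 1.0:
        log_f1 = _log_kernel(x3, x4, config.mean_x34_c1, config.var_x34, config.rho)
        log_f0 = _log_kernel(x3, x4, config.mean_x34_c0, config.var_x34, config.rho)
    else:
        sign = np.sign(config.rho)
        log_f1 = _log_kernel_degenerate(
            x3, x4, config.mean_x34_c1, config.var_x34, sign
        )
        log_f0 = _log_kernel_degenerate(
            x3, x4, config.mean_x34_c0, config.var_x34, sign
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        log_odds = (log_f1 - log_f0) + np.log(pi) - np.log1p(-pi)
    post = 1.0 / (1.0 + np.exp(-log_odds))
    # off both degenerate supports: likelihood ratio undefined -> prior
    both_off = np.isneginf(log_f1) & np.isneginf(log_f0)
    post = np.where(both_off, pi, post)
    post = np.where(np.isneginf(log_f1) & ~both_off, 0.0, post)
    post = np.where(np.isneginf(log_f0) & ~both_off, 1.0, post)
    return post


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one cohort from the generator; reproducible given a seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    z = (rng.random(n) < config.prevalence_z).astype(int)
    x12 = _bvn_draw(rng, n, config.rho, config.var_x12)
    x12 += np.where(
        z[:, None] == 1,
        np.asarray(config.mean_x12_z1),
        np.asarray(config.mean_x12_z0),
    )

    w = (rng.random(n) < 0.5).astype(int)
    x34 = _bvn_draw(rng, n, config.rho, config.var_x34)
    x34 += np.where(
        w[:, None] == 1,
        np.asarray(config.mean_x34_c1),
        np.asarray(config.mean_x34_c0),
    )

    post = posterior_prob_y(x34[:, 0], x34[:, 1], z, config)
    y = (rng.random(n) < post).astype(int)

    sample_ids = [f"S{k + 1:04d}" for k in range(n)]
    features = pd.DataFrame(
        np.column_stack([x12, x34]),
        index=sample_ids,
        columns=["X1", "X2", "X3", "X4"],
    )
    covariates = pd.DataFrame({"Z": z}, index=sample_ids)
    labels = pd.Series(y, index=sample_ids, name="Y")
    return SimulatedDataset(
        features=features,
        covariates=covariates,
        labels=labels,
        posterior=post,
        latent_class=w,
        config=config,
    )


def simulate_study1(n_samples: int = 200, seed: int | None = None) -> SimulatedDataset:
    """The uncorrelated-pairs cohort (``rho = 0``)."""
    return simulate_dataset(SimulationConfig(n_samples=n_samples, rho=0.0, seed=seed))


def default_rho_grid() -> np.ndarray:
    """Correlations -1 to 1 in steps of 0.01 (201 values)."""
    return np.round(np.arange(-100, 101) / 100.0, 2)


def _dataset_scores(data: SimulatedDataset) -> dict[tuple[str, str], float]:
    """Raw and residualized pair scores of (X1,X2) and (X3,X4) vs Y."""
    X = data.features.to_numpy()
    y = data.labels.to_numpy()
    resid = residualize(data.features, data.covariates).to_numpy()
    return {
        ("X1,X2", "raw"): pair_score(X, y, 0, 1).score,
        ("X1,X2", "residualized"): pair_score(resid, y, 0, 1).score,
        ("X3,X4", "raw"): pair_score(X, y, 2, 3).score,
        ("X3,X4", "residualized"): pair_score(resid, y, 2, 3).score,
    }


def simulate_study2(
    rho_grid=None,
    n_samples: int = 200,
    seed: int | None = None,
    replicates: int = 1,
) -> pd.DataFrame:
    """Pair scores across the correlation grid, as a tidy table.

    For each ``rho`` (and replicate) one cohort is drawn and the raw
    and residualized scores of both pairs against the outcome are
    recorded.  Columns: ``rho``, ``replicate``, ``pair``, ``variant``,
    ``score``.  Per-cell seeds derive deterministically from ``seed``.
    """
    if rho_grid is None:
        rho_grid = default_rho_grid()
    rho_grid = np.asarray(rho_grid, dtype=float)
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(
        rho_grid.size * replicates
    )
    rows = []
    idx = 0
    for rho in rho_grid:
        for rep in range(replicates):
            config = SimulationConfig(
                n_samples=n_samples, rho=float(rho), seed=int(child_seeds[idx])
            )
            idx += 1
            for (pair, variant), s in _dataset_scores(
                simulate_dataset(config)
            ).items():
                rows.append(
                    {
                        "rho": float(rho),
                        "replicate": rep,
                        "pair": pair,
                        "variant": variant,
                        "score": s,
                    }
                )
    return pd.DataFrame(rows)
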