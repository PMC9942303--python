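# Methods

## Pair discriminant scoring

For features i ≠ j the score is s_ij = |p1 − p2| with
p_c = P̂(X_i < X_j | C = c), the sample proportion of class-c profiles
in which feature i lies *strictly* below feature j. A tie
X_i == X_j therefore counts against the ordering; with continuous
abundance data ties are measure-zero, but after coarse quantization
they can depress scores, which is the conservative direction.

Equal top scores are broken by a **secondary rank score**
|mean_{C1}(R_i − R_j) − mean_{C2}(R_i − R_j)|, computed on within-profile
ranks (average rank for ties). Several variants of this tie-break
statistic circulate in the pair-classifier literature; the
between-class difference of mean within-profile rank differences is
adopted here as a convention and any residual tie is resolved
lexicographically by (i, j), making every fit deterministic. Both
statistics depend on the data only through within-profile orderings,
so all selection output is invariant under strictly increasing
per-sample transforms.

The full score table is materialized for all p(p−1)/2 pairs with a
blocked pairwise comparison (block size 128 columns) that keeps the
temporary boolean tensor near N·p·128 entries; a 698-feature,
~1000-sample table (≈243k pairs) fits comfortably.

## TSP and K-TSP rules

The classification rule follows the training orientation: if p1 < p2,
observing X_i < X_j predicts class 2, otherwise (including p1 == p2)
class 1; the complementary ordering predicts the other class. On
tie-free training data this rule's balanced accuracy is exactly
(1 + s)/2, a useful internal consistency check.

K-TSP selects disjoint pairs **greedily** along the deterministic
score ordering. The exact maximizer over all k-subsets of disjoint
pairs is a maximum-weight matching problem; greedy matches it on most
small instances (verified against exhaustive search in the tests) and
is the convention of the method's software lineage. The greedy
sequence is nested, so one pass serves every k in the grid. For each
k the criterion τ̂ divides the summed scores by the square root of the
summed within-class sample variances (ddof = 1) of the per-sample vote
count; a zero denominator (perfectly constant votes in both classes)
yields an infinite sentinel treated as maximal, and ties in τ̂ resolve
toward smaller k (parsimony). A class with a single sample contributes
zero variance. Majority voting breaks even splits with the
top-scoring pair's vote — deterministic and anchored on the most
reliable pair; this convention matters only for even k.

## Residualization

Each feature is regressed on the covariates by OLS with intercept
(solved via `numpy.linalg.lstsq`; collinearity is diagnosed with a
pivoted QR of the design and reported by column name). Residuals on
the fitting sample are exactly orthogonal to — hence uncorrelated
with — every covariate column, and residualizing twice is the
identity. Applied to held-out samples with the stored coefficients,
residuals carry no orthogonality guarantee; that is expected behavior,
not an error. Categorical covariates must be pre-encoded as indicator
columns so that reference-level choices are explicit.

In cross-validation the fold-safe default (`per_fold`) fits the
residualizer on the training folds only; a `global` mode residualizes
the entire table once, reproducing whole-dataset analyses at the cost
of train/test leakage in the regression step. Neither mode is asserted
as "the" published procedure; both are provided.

## The synthetic confounded-pair generator

The generator emulates the situation the adjustment targets, with
N = 200 samples by default:

* binary covariate Z ~ Bernoulli(0.5);
* outcome prior P(Y=1 | Z) = |Z − 0.05| (0.95 / 0.05) — a strong
  clinical risk factor;
* covariate-driven pair: (X1, X2) | Z bivariate normal with means
  (0, 5) vs (5, 0) and variance 2 (covariance 2ρ in the correlated
  study);
* outcome-driven pair: (X3, X4) generated from a **balanced latent
  component W ~ Bernoulli(0.5), independent of Z**, with means
  (0, 2.5) vs (2.5, 0) and variance 3 (covariance 3ρ);
* final outcome Y ~ Bernoulli(q) with the Bayes posterior
  q = f1·π / (f1·π + f0·(1−π)), π = |Z − 0.05|, where f_y are the two
  (X3, X4) component densities.

Drawing the latent component as a balanced coin independent of Z is
the reading that makes the construction self-consistent: the marginal
outcome prevalence is 1/2 (matching E[π]), (X3, X4) is exactly
independent of Z — so residualizing on Z barely moves its score — and
Y is associated with (X1, X2) only through Z. Had the latent component
itself been drawn from the Z-dependent prior, the posterior draw would
reproduce the component conditionals exactly, the (X3, X4) score would
sit near its population ceiling 2Φ(2.5/√6) − 1 ≈ 0.69, and the pair
would correlate with Z — neither of which the construction intends.
Because Y is a fresh posterior draw rather than the component label,
both planted pairs' scores are attenuated below their ceilings;
replicate medians at N = 200 are ≈ 0.59 (raw X1X2), ≈ 0.04
(residualized X1X2), ≈ 0.38 (raw X3X4), ≈ 0.38 (residualized X3X4).

At the grid endpoints ρ = ±1 the component covariances are singular;
draws use the exact degenerate linear map, and the posterior is
evaluated with the one-dimensional density along the support line
(points off both supports return the prior). The correlated study
produces one cohort per grid point by default; a `replicates` option
averages scores for smoother curves. Per-cell seeds derive from a
single `SeedSequence`, so every table is reproducible from one seed.

What the generator does *not* emulate: high-dimensional feature
blocks, heavy-tailed or heteroscedastic abundances, multi-level or
continuous confounders, and measurement missingness. Passing tests on
it demonstrate the selection mechanics and the decorrelation effect,
not performance on real metabolomics data.

## Cross-validation protocol

`repeated_cv` runs R iterations (default 100) of k-fold (default 5)
cross-validation, re-randomizing the partition each iteration;
stratification by class is the default because imbalanced cohorts make
unstratified folds occasionally degenerate. Fold-level confusion
matrices yield the six measures; the across-fold mean is the
per-iteration estimate. A measure with an empty denominator (PPV under
an all-negative predictor) is NaN, excluded from the fold average, and
counted. Any fit/predict estimator following the scikit-learn clone
contract can be plugged in; prediction-threshold choices for
probabilistic baselines belong to the plug-in, not the harness.

## Problem sizes in the shipped checks

The test suite and the acceptance script use 200 replicates of the
N = 200 uncorrelated study, one cohort per point of the 201-point
correlation grid, and 20×5-fold CV for the null-calibration check —
sizes at which the Monte-Carlo error of each summarized quantity is
well inside the tolerances asserted, while a full run stays under a
few minutes on one core. The correlation-grid summary is reported as
the 95th-percentile envelope of the residualized (X1, X2) score: with
201 near-null draws the plain maximum is an extreme-value statistic
(typically 0.20–0.25 at N = 200) and would misstate the
"large-majority" character of the suppression claim.

## Known limitations

* Linear OLS residualization only; heteroscedastic or nonlinear
  adjustment would need a different residualizer backend (the
  transformer interface leaves room for one).
* Binary outcomes only; no multi-class voting.
* Greedy disjoint selection can miss the exact maximum-weight pair
  set on adversarial score configurations.
* No probability outputs: TSP-family rules are hard classifiers, so
  ROC-style threshold analyses do not apply.
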