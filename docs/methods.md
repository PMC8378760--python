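# Methods

## The estimator

`droreg` fits linear regression models that are robust to adversarially
contaminated training data.  Rather than minimizing the empirical loss, the
central estimator minimizes the worst-case expected absolute residual over an
ambiguity set of probability distributions: an order-1 Wasserstein ball of
radius ε around the empirical distribution of the joint samples (x_i, y_i),
with the ground metric given by a norm ‖·‖ on the (m-dimensional) joint
(predictor, response) space.  For the absolute-residual loss this worst-case
problem relaxes exactly to the penalized program

    min_β  (1/N) Σ_i |y_i − β₀ − x_i′β|  +  ε · ‖(−β, 1)‖_*

where ‖·‖_* is the dual norm.  The penalty ‖(−β, 1)‖_* is the growth rate
(Lipschitz constant) of the loss under the chosen metric; the appended 1
accounts for transport along the response axis.  Dropping it — penalizing
β alone — corresponds to a metric with infinite response-transport cost, which
is exactly the classical ℓ1/ℓ2-regularized LAD family; the package implements
both so the difference can be measured.

Solved forms per metric:

| metric on (x, y) | dual-norm penalty κ(β)        | solver                    |
|------------------|-------------------------------|---------------------------|
| ℓ1               | max(‖β‖_∞, 1)                 | LP (HiGHS)                |
| ℓ2               | √(‖β‖₂² + 1)                  | smooth epigraph (SLSQP)   |
| ℓ∞               | ‖β‖₁ + 1                      | LP (HiGHS)                |
| M-weighted       | √((−β,1)′M⁻¹(−β,1))           | smooth epigraph (SLSQP)   |

The LPs are exact epigraph transcriptions (auxiliary variables for |residual|
and |β_j|).  For the ℓ2 and weighted metrics the penalty is globally smooth —
the response coordinate keeps the argument of the square root at least
λ_min(M⁻¹) > 0 — so the problem is a smooth convex program over the residual
epigraph; any SLSQP stationary point is the global optimum.  Solver checks in
the test suite compare every metric against a refined dense grid search of the
objective on 1–2 dimensional instances.

ℓ2-regularized LAD (penalty λ‖β‖₂, nonsmooth only at β = 0) is solved with the
surrogate √(‖β‖² + δ²), δ = 1e−10, followed by an exact-zero polish: the true
objective at the solver's point is compared against the candidate
(β = 0, intercept = median y) and the better one is returned, so the exact
zero solution is recovered whenever the penalty dominates the loss
subgradient.

**Intercept.**  The intercept is an unpenalized free variable excluded from
the transport metric: a constant coordinate has no transport interpretation,
and the worst-case relaxation above is stated for the interceptless model.
This is a documented interpretation; the benchmark scenarios all generate a
nonzero intercept.

**Ties.**  The LAD loss is piecewise linear, so optima need not be unique;
tests compare objective values rather than raw coefficients unless uniqueness
is guaranteed.

Default solver tolerances: HiGHS defaults for the LPs; SLSQP `ftol` 1e−12,
max 1000 iterations with one cold restart on failure.  A failed solve returns
`status="numerical_failure"`, never a silent wrong answer.

## Synthetic benchmark

Every sample is independently an outlier with probability q (one uniform draw
per sample, so outlier counts are Binomial(N, q), not a fixed quota).  Clean
samples: x ~ N(0, Σ) with compound-symmetric Σ (unit variance, correlation
ρ), y ~ N(β₀* + x′β*, σ²).  Outliers add N(5e, I) to x (dense_xy, dense_x,
sparse_x) or N(0, 0.25 I) (sparse_xy), and the *_xy families add a
deterministic +5σ mean shift to a clean-noise response draw.  The dense truth
is β₀* = 0.3 with twenty coefficients of 0.5; the sparse truth is β₀* = 3
with coefficients (0.05, 0, 0.006, 0, −0.007, 0, 0.008, 0, …, 0).  Noise is
parameterized either directly by σ or by SNR = β*′Σβ*/σ².  Test splits are
drawn clean-only, because the estimators are judged against the clean law.

The outlier-detection ("cloud") scenario uses 30 predictors, clean
x_j ~ N(7.5, 4²) i.i.d. and y = 0.3 + 0.5 Σ_j x_j + N(0, σ²); each outlier row
picks one center u ~ Uniform(7.5 ± 12) and sets every predictor to
Uniform(u ± 0.125), with a response exactly δ_R off the regression plane —
a tight, randomly placed cluster whose only anomaly signal is the offset.

All generation is driven by a single integer seed through NumPy's
`SeedSequence`; draws happen in a fixed order, so generation is
bit-reproducible.  What the generator does *not* emulate: heavy-tailed or
skewed noise, missing data, heteroscedasticity, or correlated contamination —
conclusions from passing tests are about Gaussian-mixture contamination only.

When the benchmark sweeps SNR, the correlation is redrawn per dataset as
0.8 × Uniform(0.2, 0.4) (one draw per dataset — the stated protocol is
ambiguous about this and the per-dataset reading is adopted); when ρ is swept
the SNR stays fixed.  Sweep defaults: 10 log-spaced SNR values in [0.05, 2]
(the point count is a choice), ρ ∈ {0.1, …, 0.9}.

## Tuning

Regularization values are selected on a single seeded 75/25 validation split
(the split fraction is a choice; the protocol prescribes one split, not
k-fold) by minimum **median absolute validation residual** — the literal
"minimum MAD on the validation set" reading, i.e. the median of |r|, not the
scale estimator about the median.  Ties break toward the smaller value for
determinism.  The candidate grid is 50 points log-spaced from 0.005·a to
a, where a = ‖X′y‖_∞ / N, with an elementwise square root applied for
absolute-deviation-loss estimators (their single-sample loss is the square
root of the squared loss).  The 1/N in the anchor keeps the candidates on the
scale of the package's mean-based losses; the classical ‖X′y‖_∞ anchor pairs
with a sum-of-squares objective, and without the normalization the whole grid
sits above the useful radius range so the validation selection saturates at
the grid boundary.  The alternative large-sample rule ε ∝ N^(−1/m) is
provided as `epsilon_from_rate` (the proportionality factor is
caller-supplied), but validation tuning is the default at benchmark sample
sizes.

## Metrics

With Δ = β̂ − β*: RR = Δ′ΣΔ / β*′Σβ* (perfect 0, null 1);
RTE = (Δ′ΣΔ + σ²)/σ² (perfect 1, null SNR+1);
PVE = 1 − (Δ′ΣΔ + σ²)/(β*′Σβ* + σ²) (perfect SNR/(SNR+1), null 0);
MSE is the mean squared prediction error on the clean test split.
RTE = RR·SNR + 1 holds algebraically and is asserted in tests.

Outlier detection flags |residual| > threshold·σ̂ with σ̂ the sample (n−1)
standard deviation of all training residuals; the ROC sweeps every distinct
|residual|/σ̂ cutoff (continuous sweep, not a grid) and AUC is the
Mann–Whitney rank statistic with ties counted ½.  Out-of-sample AUC is
measured on an independent, equally contaminated dataset.

## Generalization certificates

Under ‖(x, y)‖ ≤ R a.s. and sup ‖(−β,1)‖_* ≤ B̄, Rademacher-complexity
arguments bound the expected absolute loss by the training loss plus
2B̄R/√N + B̄R√(8 ln(2/δ)/N) with probability 1 − δ, with a companion tail
bound and inverted minimum-sample-size certificates.  Logarithms are natural.
δ is validated to (0, 1) — it is a confidence level.  R and B̄ are inputs;
the helpers that estimate them from a sample (max observed norm, penalty at
the fitted coefficients) are plug-ins, not almost-sure bounds, and the
empirical coverage test therefore uses a truncated (bounded-support) design.

## Problem sizes

The shipped benchmarks run at the small-sample scale the scenarios prescribe:
N = 100 training / M = 60 test rows with 10 replicates for the dense
estimation benchmark, N = 60 with 20 replicates for the detection benchmark,
50-point tuning grids, 50 repetitions for the Wasserstein-distance crossover
curves, and 200 replicates for the coverage check.  These sizes are the
package's test defaults; all entry points accept larger values.

## Known limitations

- The ℓ2/weighted solver is a general smooth-NLP route; a dedicated conic
  solver would scale better past a few thousand rows.
- Estimation-error theory beyond the root-N trend (restricted eigenvalues,
  Gaussian widths, sub-Gaussian norms) involves non-computable universal
  constants and is deliberately not exposed as numeric evaluators; the
  package checks the qualitative rate only.
- IRLS M-estimation inherits the classical caveat that an OLS initialization
  can be misled by high-leverage contamination; tuning constants (Huber
  1.345, Talwar 2.795, Fair 1.4) are the standard 95%-efficiency defaults,
  exposed as parameters.
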