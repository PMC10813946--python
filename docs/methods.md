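# Methods

## Model

The misrecorded (Cohen) Poisson distribution describes counts in which a
recorder misses single events: a true count `Y ~ Poisson(λ)`, `λ > 0`,
is reported faithfully unless `Y = 1`, in which case it is reported as 0
with misclassification probability `φ`.  The observed mass function is

    P(X = 0) = e^{-λ}(1 + λφ)
    P(X = 1) = e^{-λ}λ(1 - φ)
    P(X = x) = e^{-λ}λ^x / x!,   x ≥ 2.

`φ` is admitted on the closed interval `[0, 1]` so the two reductions are
representable: `φ = 0` is the plain Poisson and `φ = 1` the zero–one
modified case (no ones are ever observed).

Misrecording moves probability mass `λφe^{-λ}` from `x = 1` to `x = 0`
and changes nothing else.  Two consequences are used throughout:

* **Moments.**  Every raw moment equals the Poisson raw moment minus the
  unit contribution of the deleted ones: `E X^k = E Y^k - λφe^{-λ}`.
  With `a = φe^{-λ}`:

      E X   = λ(1 - a)
      E X²  = λ² + λ(1 - a)
      E X³  = λ³ + 3λ² + λ(1 - a)
      E X⁴  = λ⁴ + 6λ³ + 7λ² + λ(1 - a)

  and `Var X = E X² - (E X)²`.  These closed forms are checked against
  truncated series summation of `Σ x^k P(X = x)` to `1e-9` across a
  parameter grid.  (Published statements of the variance, third and
  fourth moments of this law sometimes drop a factor of `λ` in the final
  term; the series oracle pins down the forms above.)

* **Generating function.**  `G(s) = e^{λ(s-1)} + λφe^{-λ}(1 - s)`: the
  Poisson pgf plus a linear correction.  This is the unique reading
  consistent with `G(1) = 1` and `G'(1) = E X`, both asserted in tests.

Sampling uses the mechanism directly (Poisson draw, then thinning of the
ones) rather than CDF inversion: it is O(1) per draw, exact, and makes
the generator a faithful emulation of the data-generating story.  Every
stochastic function takes a seed or `numpy.random.Generator` argument;
nothing draws from global state.

## Maximum-likelihood estimation

With `n0` and `n1` the observed counts of zeros and ones, `N` the sample
size and `x̄` the sample mean, the log-likelihood is

    ℓ(λ, φ) = -Nλ + n0 log(1 + φλ) + n1 log(1 - φ) + Nx̄ log λ - Σ log xᵢ!

and the score equations reduce to a quadratic in λ:

    λ² - (x̄ - 1 + n0/N) λ - (x̄ - n1/N) = 0,

whose positive root, followed by `φ̂ = (n0 - n1/λ̂)/(n0 + n1)`, is the
MLE.  Since `x̄ ≥ n1/N` for any integer sample the discriminant is
always nonnegative.  Conventions for degenerate inputs:

* all-zero samples (`x̄ = 0`): the likelihood degenerates to `λ̂ = 0`;
  the fit raises an error rather than returning a boundary value;
* no zeros or ones (`n0 + n1 = 0`): `φ` is not identified; the error
  raised carries the still-valid `λ̂`;
* `x̄ = n1/N` exactly: the nonnegative root is `max(x̄ - 1 + n0/N, 0)`,
  and a zero root is treated as failure;
* one-inflated samples can drive `φ̂` below 0 (or, in principle, above
  1).  The raw value is reported with a warning; an opt-in `clamp` mode
  truncates to `[0, 1]`.  Silent clamping is never done because it would
  bias simulation MSEs.

The closed form is validated against direct numerical maximisation of
the log-likelihood (coarse grid + Nelder–Mead refinement) on random
small samples to `1e-4`.

## Linear Bayes estimation

The MLE can be written `θ̂_MLE = A T` with `T = (t1, t2) = (2λ̂,
n0 - n1/λ̂)` and the diagonal design matrix `A = diag(1/2, 1/(n0+n1))`.
Given any prior on `θ = (λ, φ)` with finite second moment — only its
mean `Eθ` and covariance `Cov(θ)` enter — the linear Bayes estimator is
the linear function `B T + b` of `T` that is unbiased under the joint
(prior × sampling) model and minimises Bayes risk under squared loss:

    M = [W + A⁻¹ Cov(θ) (A⁻¹)']⁻¹
    B = A - A W M
    b = Eθ - B A⁻¹ Eθ,

where `W = E[Cov(T | θ)] = diag(Var t1, Var t2)` is the sampling
dispersion of `T`.  (The positive-definite weight matrix of the squared
loss cancels in the minimisation and is not represented.)  Equivalently
`θ̂_LB = (A - AWM) T + AWM A⁻¹ Eθ`: a matrix-weighted average of the
MLE and the prior mean, with the weight on the prior growing in `W`
(noisier data) and shrinking in `Cov(θ)` (vaguer prior).  Three limits
are asserted as tests: `Cov(θ) → ∞` recovers the MLE, `Cov(θ) → 0`
collapses to the prior mean, and `W = 0` equals the MLE exactly.

Under the joint model the MSE matrices are `MSEM(θ̂_MLE) = A W A'` and
`MSEM(θ̂_LB) = A(W - WMW)A'`, so the gap `A W M W A'` is positive
semi-definite: the linear Bayes estimator never loses in the Loewner
ordering when the prior is correctly specified.  This is enforced as a
property test over random configurations (smallest eigenvalue
`≥ -1e-10`) and checked empirically by simulation from the joint model.

### Bootstrap estimation of W

`W` is unknown in practice and is estimated by resampling the `N`
observations with replacement (implemented as multinomial draws over the
observed support, which is equivalent and vectorises), recomputing
`(t1*, t2*)` from each resample's own summary, and taking the diagonal
of sample variances.  Resamples on which the statistic is undefined (no
zeros or ones, or all zeros) are dropped with a warning; fewer than two
valid resamples is an error.  The design matrix `A` is held at the
observed sample's `n0 + n1` throughout: the estimator treats `A` as the
known design of the data actually seen, while the resample-to-resample
variation of the counts is exactly what the variance of `t2*` measures.
Default bootstrap size is 1000 for single fits and 500 inside simulation
studies (where it sits in the replication loop).

### Prior specification

The prior enters only through `(Eθ, Cov(θ))`.  In the packaged empirical
examples the natural prior mean is the truth computed from the original
(unaltered) dataset; the prior covariance is the user's choice, with
`diag(0.1², 0.1²)` as the CLI default — a standard deviation of 0.1 on
each component, loose enough that the data dominate.  Inside simulation
studies the prior mean is placed at the generating truth and the
covariance defaults to `diag(0.01, 0.01)`; a tight, correctly-centred
prior is the regime in which the linear Bayes estimator's advantage is
visible, and the washout limit doubles as a consistency check against
the MLE.

## Monte-Carlo study

One replication: generate `N` observations at the true `(λ, φ)`, fit
the MLE, bootstrap `W` on that same dataset, fit the linear Bayes
estimator with the truth-centred prior.  One cell: `J` replications
aggregated into component means, component-averaged MSEs for both
estimators, and the Euclidean distance between the two per-component
MSE 2-vectors.  Defaults follow the regime the estimators are meant
for — rare events (`λ` below ~1, substantial `φ`), `N = 200` or 800,
`J = 100`, bootstrap size 500.  Replications draw from independent
substreams seeded by `(study seed, replication index)`, so studies are
byte-reproducible and order-independent; degenerate replications are
dropped and counted, never imputed.

**MSE convention.**  The summed quadratic `E[(θ̂-θ)'(θ̂-θ)]` and its
per-component average differ by a factor of 2; published worked values
for this model follow the average convention, which the package reports
as `mse_avg` (the sum is kept alongside as `mse_sum`).  The scalar MSE
columns and the printed "Euclidean distance" in the reference simulation
tables cannot be reconciled under any single-number reading
(`|MSE_MLE - MSE_LB|` does not equal the printed distance), so the
package defines the distance as the norm of the difference of the
per-component MSE vectors and documents the discrepancy; no acceptance
quantity depends on it.

## What the synthetic generator does and does not emulate

The generator reproduces i.i.d. sampling from the misrecorded law with a
constant, state-independent misclassification probability.  Real
misrecorded counts may have recorder effects that vary over time,
misclassification of values other than one, or overdispersion relative
to the Poisson base — none of which are modelled.  Passing tests
therefore demonstrate correctness of the estimators *under the model's
own assumptions*, not robustness to their violation.

## Numerical choices

* Series evaluations truncate where the Poisson tail (which bounds the
  misrecorded tail beyond `x = 1`) falls below `1e-12`.
* All 2×2 inversions are closed-form with a determinant-magnitude guard
  (`|det| > 1e-300`) and raise naming the offending matrix; no general
  linear solver is involved.
* Log-likelihood returns `-inf` (not an exception) for invalid
  parameters, so numerical optimisers can traverse the boundary.
* Problem sizes in the test suite — bootstrap sizes of a few hundred,
  `J` of 60–500, `2×10⁴` replicates in the joint-model unbiasedness
  check — were chosen so each check's Monte-Carlo error is comfortably
  below the tolerance it asserts.

## Known limitations

* The empirical linear-Bayes point values for the packaged datasets
  depend on the unstated prior covariance and bootstrap configuration of
  whoever fits them; the package therefore treats the MLE worked values
  as exact references and the linear-Bayes comparison as a dominance
  (ordering) property rather than a point reproduction.
* `φ̂` outside `[0, 1]` is possible and reported raw; users who need a
  proper probability must opt into clamping or use a prior.
* No confidence intervals or asymptotic variance formulas are provided,
  and no fully Bayesian posterior computation — avoiding the latter is
  the point of the linear Bayes construction.
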