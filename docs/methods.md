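# Methods

## The family

For a baseline lifetime cdf *F*(*x*; *ζ*) the log-expo transform defines

G(x; λ, ζ) = log(2 − e^{−λF(x;ζ)}) / log(2 − e^{−λ}).

*λ* is a pure shape parameter: the transform re-weights probability mass
along the baseline's own time scale and neither shifts the support nor
changes the tail index.  G → F pointwise as λ → 0, so the baseline is the
continuity limit of the family rather than a member of it (λ = 0 is a
removable singularity of the formula).

**Admissible domain.**  The classical presentation of this construction
takes λ > 0, but 2 − e^{−λF} remains positive for every F ∈ [0,1] whenever
λ > −log 2, and fitted real data can demand negative λ̂ (one published
application of this family reports λ̂ = −0.69).  The package therefore
admits λ ∈ (−log 2, 0) ∪ (0, ∞) in the distributional calculus and in
`fit_mle`'s default (`lam_domain="full"`), with the positive half-line
available as `lam_domain="positive"`.  Values with |λ| < 1e−8 are evaluated
as the baseline itself; this threshold keeps the 0/0 limit away from
floating-point cancellation while being far below any statistically
resolvable λ.

**Numerical form.**  Every occurrence of log(2 − e^{−y}) is computed as
`log1p(−expm1(−y))`, which is exact at y = 0 and loses no digits for small
|y|; survival is computed as (L(λ) − L(λF))/L(λ) with L that stable
logarithm, so log-survival terms of censored likelihoods do not cancel.
For λ < 0 both λ and L(λ) are negative; densities are evaluated through
log|λ| − log|L(λ)| so they remain positive on the whole admissible domain.

**Baselines.**  Fréchet (cdf exp[−(β/x)^α]; the "(βx)" typography seen in
some sources is read as β/x, the only version that is an increasing proper
cdf consistent with the stated density αβ^α x^{−α−1}e^{−(β/x)^α}),
Exponential (rate α), Lomax (1 − (1+αx)^{−β}) and Weibull
(1 − e^{−(x/λ)^c}, the textbook shape/scale convention).  Closed-form
vectorized cdf/pdf/logpdf/ppf are implemented directly because likelihood
optimization and the study engine evaluate them millions of times; the
equivalent frozen scipy distribution backs random variate generation and
serves as an independent cross-check in the tests.  All four baselines have
analytic quantiles, so LET quantiles and inverse-cdf sampling are exact;
a user-registered baseline without an analytic inverse can rely on its
scipy `ppf` (Brent root-finding internally).

## Moments

Raw moments are computed in quantile space, E[X^n] = ∫₀¹ Q(u)^n du, which
avoids unbounded-domain quadrature.  Fréchet-type tails concentrate the
integral's difficulty at u → 1, where Q(u) diverges like (1−u)^{−1/α}; the
integral is split at u₀ = 1 − 10⁻⁴ and the tail is evaluated in x-space as
∫ x^n g(x) dx over (Q(u₀), ∞), where adaptive quadrature on a semi-infinite
interval handles the power-law decay well.  Quadrature tolerances are
1e−10 relative / 1e−12 absolute per piece; reproduced reference-table values
agree to ~1e−4 relative, limited by the 4-digit printing of the table, not
by the quadrature.

Moment existence is decided analytically (order < α for Fréchet, < β for
Lomax); scipy's numerical `moment` is not trusted here because it returns
spurious finite values for divergent integrals.  Published moment tables
for this family print u₂′ − u₁′² in their "SD" row (every column matches the
variance, none its square root), so `moment_summary` reports both `variance`
and `sd` and table comparisons are made against the variance.

## Estimation

Likelihoods: complete data uses Σ log g; Type-II uses the order-statistic
likelihood with its combinatorial constant log(n!/t!) included (so the value
matches the printed definition; the constant cancels in all comparisons and
is excluded from the type-II ↔ random cross-identity); Type-I uses
(n−δ) log S(x_c) + Σ_{events} log g; random censoring uses
Σ I log g + Σ (1−I) log S.  The printed score equations of the family are
used as finite-difference cross-checks in the test-suite, not as the solver
(their typeset versions contain inconsistencies: a spurious 1/F factor in
the Type-II ζ-score, and a misplaced log in the k₁ factor of the λ-score —
the likelihoods themselves are taken as authoritative).

`fit_mle` maximizes the scheme-appropriate log-likelihood with Nelder-Mead
(xatol = fatol = 1e−9) on transformed parameters: log for positive baseline
parameters, log(λ + log 2) for the full λ domain, log λ for the positive
domain.  Data-analysis fits are multi-start by default — λ ∈
{−0.5, 0.2, 1, 3} (positive subset under `lam_domain="positive"`) crossed
with three baseline starts seeded by scipy's plain-baseline fit of the
uncensored observations and ×0.5/×2 perturbations — and the best converged
start is retained.  On the bundled leukemia data this multi-start scheme
reaches the same optimum as a global differential-evolution search.
Non-convergence is reported, never silently replaced.

Standard errors come from the inverse observed information, the central
finite-difference Hessian (relative step 1e−4) of the negative
log-likelihood at the estimate in natural parameter space.  Non-positive
-definite Hessians and λ̂ within 1e−4 of the −log 2 boundary yield NaN
(flagged unavailable) rather than a number.

The submodel test T = −2(llᵣ − ll) is referred to χ²₁.  The null λ = 0 sits
at the family's removable singularity, so the usual regularity conditions
hold only in the limit; the χ²₁ calibration is the convention used in the
literature for this construction, and a Monte Carlo check in the test-suite
confirms the nominal-5% size lands in the classical [2%, 9%] band under a
Fréchet null.

## Cure-fraction and logarithmic-transform competitors

Two distinct models are both called "long-term" in the lifetime literature;
the package keeps them apart.  `LogTransformModel` is the parameter-free
enrichment G = 1 − log(2 − F)/log 2 (the construction the LET generalizes).
It is provably not a member of the LET family: over the positive-λ range the
closest LET model with the same baseline stays > 0.01 away in sup-distance;
allowing negative λ the gap narrows (≈ 0.0016 at λ ≈ −0.29 for a Fréchet(2,1)
baseline) but never closes.  `LongTermModel` is the mixture
S*(x) = p + (1−p)S(x) with cure probability p ∈ [0, 1); its fit maximizes
the standard random-censoring likelihood with the improper event sub-density
(1−p)f, with p on the logit scale.  The Kaplan–Meier estimator wraps
lifelines; an independent hand-rolled product-limit computation checks it in
the tests.

## Monte Carlo study engine

`run_study` draws inverse-cdf samples (child seed = master seed + rep
index), applies the censoring scheme, fits, and accumulates per-parameter
mean/bias/MSE, excluding and counting non-converged replications (cells
with > 20% failures are flagged).  Design choices where the published
description is silent:

- **Type-II rounding:** t = ⌊fraction·n⌋ censored observations, replaced by
  the (n−t)-th order statistic.
- **Type-I cutoff:** x_c is the true model's (1−fraction) quantile, the
  choice that makes the expected censored share equal the nominal fraction.
- **Study fits** are a single truth-initialized Nelder-Mead local
  optimization with λ constrained positive (`lam_domain="positive"`,
  `multistart=False`).  Truth-started local fitting is the standard design
  for consistency studies of a family with a flat α–λ likelihood ridge;
  best-of-multistart fitting instead reports each replicate's global
  optimum, which drifts along the ridge (and, on the full λ domain under
  Type-II censoring, escapes to the λ → −log 2 boundary with inflated α̂).
  Published simulation tables for this family are consistent with the
  positive-domain truth-anchored design and are not reproducible under
  ridge-drifting alternatives, which remain available through `fit_kwargs`.
- **Replications:** the package's reference runs use N = 1000 (the
  published tables used 10,000); N is a config field.  At N = 1000 the
  Monte Carlo standard error of a mean α̂ is ≈ 0.02–0.03 for the
  configurations exercised in the tests.

What the generator emulates: i.i.d. lifetimes from a fully specified LET
model, censored by the three designed mechanisms.  It does not emulate
covariates, dependence between lifetime and censoring beyond the designed
schemes, ties from coarse measurement, or model misspecification — so
passing tests demonstrate correctness of the machinery and consistency of
the estimators under the model, not robustness on real data.

## Known limitations

- Individual parameters of the transformed Fréchet are weakly identified in
  small samples (flat α–λ ridge); log-likelihood and AIC are stable, point
  estimates and their SEs much less so.
- KS/W*/A p-values treat parameters as known (no Lilliefors-type
  correction), matching common published practice; they are comparative
  indices, not exact test sizes.
- The χ²₁ calibration of the submodel test ignores possible boundary
  effects at the λ = 0 singularity.
- Bayesian estimation, DIC, and interval censoring are out of scope.
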