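# letdist

Parametric survival analysis with **log-expo transformed (LET) lifetime
distributions** — a one-parameter enrichment of any baseline lifetime law —
for biostatisticians and reliability analysts who need flexible parametric
fits to complete or right-censored time-to-event data.

## The model

Given a baseline cdf *F*(*x*; *ζ*) on [0, ∞), the log-expo transform adds a
shape parameter *λ*:

```
G(x; λ, ζ) = log(2 − e^{−λ F(x;ζ)}) / log(2 − e^{−λ}),
g(x; λ, ζ) = λ f(x;ζ) e^{−λ F(x;ζ)} / [log(2 − e^{−λ}) (2 − e^{−λ F(x;ζ)})].
```

The transform is the identity as *λ* → 0 and defines a proper distribution
for every *λ* ∈ (−log 2, 0) ∪ (0, ∞).  Because the quantile function is
available in closed form whenever *F*⁻¹ is, exact inverse-cdf sampling and
quantile-space moment quadrature come for free.

The package provides:

- **Distributional calculus** (`letdist.generator`): cdf, pdf, survival,
  hazard, reverse hazard, quantile and sampling for a LET model over any
  registered baseline (Fréchet, Exponential, Lomax, Weibull built in).
- **Moments** (`letdist.moments`): raw moments by adaptive quadrature with
  heavy-tail handling, plus SD/variance, skewness and kurtosis.
- **Estimation** (`letdist.estimation`): log-likelihoods and multi-start ML
  fitting for complete, Type-II, Type-I and randomly censored samples;
  observed-information standard errors; a χ²₁ likelihood-ratio test of the
  baseline against its LET extension.
- **Goodness of fit** (`letdist.gof`): Kolmogorov–Smirnov (with asymptotic
  p-value), Cramér–von Mises W\*, Anderson–Darling A, AIC.
- **Competitor families** (`letdist.longterm`): the fixed logarithmic
  transform `G = 1 − log(2 − F)/log 2` and cure-fraction (long-term
  survivor) mixtures `S*(x) = p + (1 − p) S(x)`, plus a Kaplan–Meier
  estimator.
- **Monte Carlo engine** (`letdist.simulation`): simulate → censor → fit →
  mean/bias/MSE tables for consistency studies.
- **Data** (`letdist.datasets`): `time,event` CSV I/O and the bundled
  46-patient leukemia-recurrence dataset (33 events, 13 censored).

## Worked example

Moments of the LET-Fréchet model with λ=3, α=6, β=2:

```sh
$ letdist moments --model let-frechet --lam 3 -p 6 -p 2
{
  "u1p": 1.8825853846643283,
  "u2p": 3.642933086004778,
  "u3p": 7.34390599670408,
  "u4p": 15.944252358692943,
  "variance": 0.09880535545304125,
  "sd": 0.31433319177751695,
  "cs": 3.6626665580020723,
  "ck": 43.60860065070133
}
```

The mean lifetime is 1.88, the variance 0.0988, and the distribution is
strongly right-skewed (skewness 3.66) with very heavy tails (kurtosis 43.6)
— the Fréchet tail survives the transform.

Fitting the LET-Fréchet to the bundled leukemia recurrence data under random
censoring:

```sh
$ letdist fit --data fixture:leukemia46 --model let-frechet
{
  "model": "let-frechet",
  "params": {
    "lam": 0.9160040449591929,
    "alpha": 0.4651186307373689,
    "beta": 0.9641849465176917
  },
  "se": {
    "lam": 3.423467941123685,
    "alpha": 0.27857588222128155,
    "beta": 2.6407523440614633
  },
  "loglik": -45.798109622817265,
  "aic": 97.59621924563453,
  "converged": true
}
```

The maximized log-likelihood is −45.80 (AIC 97.60).  The large standard
errors on λ̂ and β̂ reflect a genuinely flat likelihood ridge: α and λ trade
off against each other in this family, so individual parameters are weakly
identified on 46 observations even when the fit itself is stable.  The same
library calls are available programmatically:

```python
import letdist as ld

sample = ld.load_fixture("leukemia46").sample
fit = ld.fit_mle(sample, baseline="frechet")
cure = ld.fit_lt_model(sample, base="frechet")   # cure-fraction competitor
print(fit.loglik, fit.aic, cure.loglik, cure.aic)
```

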