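"""Competitor families: logarithmic transform and cure-fraction models.

Two distinct constructions share the name "long-term Fréchet" in the
lifetime literature, so they are kept strictly apart here:

``lt2`` (logarithmic transform)
    The fixed, parameter-free enrichment ``G(x) = 1 - log(2 - F(x))/log 2``
    of a baseline cdf — the construction the log-expo transform generalizes
    by adding a shape parameter.  Registered as ``lt2-<baseline>``.

``cure`` (long-term survivor / cure fraction)
    The mixture survival function ``S*(x) = p + (1 - p) S(x)`` in which a
    fraction ``p`` of the population never experiences the event.  The event
    sub-density ``(1 - p) f(x)`` integrates to ``1 - p``; the remaining mass
    ``p`` sits at infinity.  Registered as ``cure-<baseline>``.

A Kaplan-Meier product-limit estimator (backed by lifelines) is provided for
visual comparison of fitted survival curves with censored data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special

from .baselines import BaselineModel, ParameterError, get_baseline
from .estimation import FitResult, SurvivalSample, _fd_hessian, _minimize, standard_errors

__all__ = [
    "LogTransformModel",
    "eq2_transform_cdf",
    "eq2_transform_pdf",
    "LongTermModel",
    "lt_survival",
    "fit_lt_model",
    "kaplan_meier",
    "KaplanMeierEstimate",
]

_LOG2 = np.log(2.0)


# ---------------------------------------------------------------------------
# logarithmic transform (the one-parameter-poorer competitor)
# ---------------------------------------------------------------------------

def eq2_transform_cdf(x, baseline: BaselineModel):
    """cdf of the logarithmic transform: ``1 - log(2 - F(x)) / log 2``."""
    F = baseline.cdf(x)
    return 1.0 - np.log(2.0 - F) / _LOG2


def eq2_transform_pdf(x, baseline: BaselineModel):
    """pdf of the logarithmic transform: ``f(x) / [log 2 * (2 - F(x))]``."""
    return baseline.pdf(x) / (_LOG2 * (2.0 - baseline.cdf(x)))


@dataclass(frozen=True)
class LogTransformModel:
    """Logarithmic transform of a baseline; no extra parameter."""

    baseline: BaselineModel

    def cdf(self, x):
        return eq2_transform_cdf(x, self.baseline)

    def pdf(self, x):
        return eq2_transform_pdf(x, self.baseline)

    def sf(self, x):
        return np.log(2.0 - self.baseline.cdf(x)) / _LOG2

    def ppf(self, u):
        # u = 1 - log(2 - F)/log2  =>  F = 2 - 2^(1-u)
        u = np.asarray(u, dtype=float)
        return self.baseline.ppf(2.0 - np.exp2(1.0 - u))


# ---------------------------------------------------------------------------
# cure-fraction (long-term survivor) mixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LongTermModel:
    """Cure-fraction model ``S*(x) = p + (1 - p) S(x)``.

    ``p`` in ``[0, 1)`` is the probability of being cured (never failing);
    ``base`` supplies the susceptible sub-population's survival ``S``.
    """

    p: float
    base: BaselineModel

    def __post_init__(self):
        if not (0.0 <= self.p < 1.0):
            raise ParameterError(f"cure probability p must lie in [0, 1), got {self.p}")

    def sf(self, x):
        return lt_survival(x, self)

    def cdf(self, x):
        return (1.0 - self.p) * self.base.cdf(x)

    def pdf(self, x):
        """Event sub-density ``(1 - p) f(x)``; integrates to ``1 - p``."""
        return (1.0 - self.p) * self.base.pdf(x)


def lt_survival(x, model: LongTermModel):
    """Long-term survival ``p + (1 - p) S(x)``, tending to ``p`` as x grows."""
    return model.p + (1.0 - model.p) * model.base.sf(x)


def fit_lt_model(
    sample: SurvivalSample,
    base: str = "frechet",
    init: Optional[Sequence[float]] = None,
    compute_se: bool = True,
) -> FitResult:
    """Fit a cure-fraction model to randomly censored data by ML.

    Maximizes ``sum_I log[(1-p) f(x)] + sum_(1-I) log[p + (1-p) S(x)]`` over
    ``(p, *zeta)`` with ``p`` on the logit scale and positive baseline
    parameters on the log scale, from a grid of starts.
    """
    times, events = sample.times, sample.events.astype(bool)

    def negll_raw(theta: np.ndarray) -> float:
        p, zeta = theta[0], theta[1:]
        if not (0.0 <= p < 1.0) or np.any(zeta <= 0):
            return np.inf
        try:
            b = get_baseline(base, *zeta)
        except (ValueError, ParameterError):
            return np.inf
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.sum(np.log1p(-p) + b.logpdf(times[events])) if events.any() else 0.0
            if (~events).any():
                ll += np.sum(np.log(p + (1.0 - p) * b.sf(times[~events])))
        return -ll if np.isfinite(ll) else np.inf

    def negll_opt(x: np.ndarray) -> float:
        p = float(special.expit(x[0]))
        return negll_raw(np.concatenate(([p], np.exp(x[1:]))))

    # p starts span low to moderate cure mass; baseline starts around crude scales
    zeta0 = {
        "frechet": [(0.7, 0.4), (0.5, 1.0), (1.5, 0.5)],
        "weibull": [(1.0, 1.0), (0.7, 2.0), (1.5, 0.5)],
        "exponential": [(1.0 / max(times.mean(), 1e-12),)],
        "lomax": [(1.0, 2.0)],
    }.get(base, [(1.0, 1.0)])
    starts = [np.concatenate(([p0], z)) for p0 in (0.05, 0.2, 0.4) for z in zeta0]
    if init is not None:
        starts.insert(0, np.asarray(init, dtype=float))

    best, n_evals = None, 0
    for theta0 in starts:
        p0 = np.clip(theta0[0], 1e-4, 1 - 1e-4)
        x0 = np.concatenate(([np.log(p0 / (1 - p0))], np.log(theta0[1:])))
        if not np.isfinite(negll_opt(x0)):
            continue
        res = _minimize(negll_opt, x0)
        n_evals += res.nfev
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res

    param_names = ("p",) + get_baseline(base, *zeta0[0]).param_names
    if best is None:
        return FitResult(
            param_names=param_names, estimates=np.full(len(param_names), np.nan),
            loglik=-np.inf, converged=False, n_evals=n_evals, k=len(param_names),
            aic=np.inf, message="no start converged",
        )
    p_hat = float(special.expit(best.x[0]))
    theta_hat = np.concatenate(([p_hat], np.exp(best.x[1:])))
    loglik = -best.fun
    k = len(param_names)
    model = LongTermModel(p_hat, get_baseline(base, *theta_hat[1:]))
    fit = FitResult(
        param_names=param_names, estimates=theta_hat, loglik=loglik,
        converged=bool(best.success), n_evals=n_evals, k=k,
        aic=2 * k - 2 * loglik, model=model, message=best.message, _negll=negll_raw,
    )
    if compute_se and fit.converged:
        fit.se = standard_errors(fit, sample)
    return fit


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KaplanMeierEstimate:
    """Right-continuous, non-increasing product-limit survival estimate."""

    times: np.ndarray
    survival: np.ndarray

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        idx = np.searchsorted(self.times, x, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out if out.ndim else float(out)


def kaplan_meier(sample: SurvivalSample) -> KaplanMeierEstimate:
    """Kaplan-Meier estimator of the survival function of a censored sample."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(sample.times, event_observed=sample.events)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    return KaplanMeierEstimate(times=times, survival=surv)
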