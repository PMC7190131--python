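"""Empirical-distribution goodness-of-fit statistics for uncensored samples.

All three statistics are functions of the probability-integral transforms
``u_(i) = G(x_(i))`` of the ordered sample under the candidate model, so they
are invariant under input ordering and under any common strictly monotone
transformation of data and model.

The KS p-value is taken from the asymptotic Kolmogorov distribution with the
model treated as fully known.  No Lilliefors-type correction for estimated
parameters is applied: published comparisons of fitted lifetime models
customarily report the plain asymptotic p-value, and the correction would
change the statistic's null distribution in a model-specific way.  Treat the
p-values as a comparative index rather than an exact test size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import kolmogorov

__all__ = ["GofReport", "ks_test", "cramer_von_mises", "anderson_darling", "aic", "gof_report"]

_CLIP = 1e-12


def _transform(sample, model_cdf: Callable) -> np.ndarray:
    x = np.sort(np.asarray(sample, dtype=float))
    if x.size < 1:
        raise ValueError("empty sample")
    u = np.asarray(model_cdf(x), dtype=float)
    return u


def _as_cdf(model) -> Callable:
    if callable(model):
        return model
    if hasattr(model, "cdf"):
        return model.cdf
    raise TypeError("model must be a callable cdf or expose a .cdf method")


@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float


def ks_test(sample, model) -> KSResult:
    """Kolmogorov-Smirnov distance of a sample from a model cdf.

    ``D = max_i max(i/n - u_(i), u_(i) - (i-1)/n)`` with the asymptotic
    Kolmogorov p-value ``P(sqrt(n) D)``.
    """
    u = _transform(sample, _as_cdf(model))
    n = u.size
    if n < 2:
        raise ValueError("KS test needs at least 2 observations")
    i = np.arange(1, n + 1)
    d = np.maximum(i / n - u, u - (i - 1) / n).max()
    return KSResult(statistic=float(d), p_value=float(kolmogorov(np.sqrt(n) * d)))


def cramer_von_mises(sample, model) -> float:
    """Cramér-von Mises statistic ``W* = 1/(12n) + sum [u_(i) - (2i-1)/(2n)]^2``."""
    u = _transform(sample, _as_cdf(model))
    n = u.size
    i = np.arange(1, n + 1)
    return float(1.0 / (12 * n) + np.sum((u - (2 * i - 1) / (2 * n)) ** 2))


def anderson_darling(sample, model) -> float:
    """Anderson-Darling statistic ``A = -n - mean((2i-1)[log u_(i) + log(1-u_(n+1-i))])``.

    Transforms exactly equal to 0 or 1 are clipped at 1e-12 (with a warning)
    to keep the logarithms finite.
    """
    u = _transform(sample, _as_cdf(model))
    n = u.size
    if np.any((u <= 0) | (u >= 1)):
        import warnings

        warnings.warn("probability transforms at 0 or 1 clipped to [1e-12, 1-1e-12]")
        u = np.clip(u, _CLIP, 1 - _CLIP)
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(u) + np.log(1 - u[::-1]))))


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion ``2k - 2 loglik``."""
    return 2.0 * k - 2.0 * loglik


@dataclass(frozen=True)
class GofReport:
    ks: float
    ks_p_value: float
    w_star: float
    a_star: float
    aic: float


def gof_report(sample, model, loglik: float, k: int) -> GofReport:
    """Bundle KS, W*, A and AIC for one fitted model on an uncensored sample."""
    ks = ks_test(sample, model)
    return GofReport(
        ks=ks.statistic,
        ks_p_value=ks.p_value,
        w_star=cramer_von_mises(sample, model),
        a_star=anderson_darling(sample, model),
        aic=aic(loglik, k),
    )
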