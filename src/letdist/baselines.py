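"""Baseline lifetime distributions and a registry for user-supplied ones.

A baseline is any proper lifetime distribution on ``[0, inf)`` described by
its cdf ``F(x; zeta)`` and pdf ``f(x; zeta)``.  The log-expo transform in
:mod:`letdist.generator` enriches an arbitrary baseline with one extra shape
parameter.

The built-in families carry closed-form vectorized cdf/pdf/log-pdf/quantile
implementations — likelihood optimization and the Monte Carlo study engine
evaluate them millions of times, so the per-call overhead of a generic
distribution object matters.  The equivalent frozen ``scipy.stats``
distribution is available lazily as ``.dist`` (used for random variates and
as an independent cross-check in the test-suite).

Built-in baselines
------------------
``frechet``      heavy-tailed inverse-Weibull law, cdf ``exp[-(beta/x)^alpha]``
``exponential``  constant-hazard law with rate ``alpha``
``lomax``        Pareto-type law, cdf ``1 - (1 + alpha*x)^-beta``
``weibull``      cdf ``1 - exp[-(x/lam)^c]`` (textbook shape/scale convention)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "BaselineModel",
    "ParameterError",
    "make_frechet",
    "make_exponential",
    "make_lomax",
    "make_weibull",
    "get_baseline",
    "BASELINE_REGISTRY",
]


class ParameterError(ValueError):
    """Raised when a distribution parameter is outside its admissible range."""


@dataclass(frozen=True)
class BaselineModel:
    """A named lifetime distribution with cdf/pdf/quantile access.

    Parameters
    ----------
    name : str
        Registry key, e.g. ``"frechet"``.
    params : tuple of (str, float)
        Ordered parameter vector ``zeta`` (name, value pairs).
    fns : dict
        Closed-form callables ``cdf``, ``sf``, ``pdf``, ``logpdf``, ``ppf``.
    dist_factory : callable
        Zero-argument factory for the matching frozen scipy distribution.
    support : (float, float)
        Closure of the support; lower bound is >= 0 for lifetime laws.
    """

    name: str
    params: tuple[tuple[str, float], ...]
    fns: dict = field(repr=False)
    dist_factory: Callable = field(repr=False)
    support: tuple[float, float] = (0.0, np.inf)

    @property
    def zeta(self) -> np.ndarray:
        return np.array([v for _, v in self.params], dtype=float)

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(k for k, _ in self.params)

    @property
    def dist(self):
        """Frozen scipy.stats equivalent (created on first access)."""
        cached = self.__dict__.get("_dist")
        if cached is None:
            cached = self.dist_factory()
            object.__setattr__(self, "_dist", cached)
        return cached

    def cdf(self, x):
        return self.fns["cdf"](np.asarray(x, dtype=float))

    def sf(self, x):
        return self.fns["sf"](np.asarray(x, dtype=float))

    def pdf(self, x):
        return self.fns["pdf"](np.asarray(x, dtype=float))

    def logpdf(self, x):
        return self.fns["logpdf"](np.asarray(x, dtype=float))

    def ppf(self, u):
        """Analytic inverse cdf; u = 0 and 1 map to the support edges."""
        return self.fns["ppf"](np.asarray(u, dtype=float))


def _edge(fn, u):
    # evaluate a closed-form quantile, keeping u = 1 -> +inf silent
    with np.errstate(divide="ignore"):
        return fn(u)


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ParameterError(f"{name} must be a positive finite number, got {value!r}")


def make_frechet(alpha: float, beta: float) -> BaselineModel:
    """Fréchet baseline with cdf ``exp[-(beta/x)^alpha]`` on ``x > 0``.

    ``alpha`` is the tail (shape) parameter — raw moments of order ``n`` are
    finite iff ``n < alpha`` — and ``beta`` is the scale.  Equivalent to
    ``scipy.stats.invweibull(alpha, scale=beta)``.
    """
    _require_positive(alpha=alpha, beta=beta)
    a, b = float(alpha), float(beta)

    def _t(x):  # (beta/x)^alpha with the x<=0 edge mapped to +inf
        with np.errstate(divide="ignore"):
            return np.where(x > 0, (b / np.where(x > 0, x, 1.0)) ** a, np.inf)

    def logpdf(x):
        with np.errstate(divide="ignore"):
            return np.where(
                x > 0,
                np.log(a) + a * np.log(b) - (a + 1) * np.log(np.where(x > 0, x, 1.0)) - _t(x),
                -np.inf,
            )

    def ppf(u):
        with np.errstate(divide="ignore"):
            return b * (-np.log(u)) ** (-1.0 / a)

    fns = dict(
        cdf=lambda x: np.exp(-_t(x)),
        sf=lambda x: -np.expm1(-_t(x)),
        pdf=lambda x: np.where(x > 0, np.exp(logpdf(x)), 0.0),
        logpdf=logpdf,
        ppf=ppf,
    )

    def factory():
        from scipy import stats

        return stats.invweibull(c=a, scale=b)

    return BaselineModel(
        name="frechet", params=(("alpha", a), ("beta", b)), fns=fns, dist_factory=factory
    )


def make_exponential(alpha: float) -> BaselineModel:
    """Exponential baseline with rate ``alpha``: cdf ``1 - exp(-alpha*x)``."""
    _require_positive(alpha=alpha)
    a = float(alpha)
    fns = dict(
        cdf=lambda x: np.where(x > 0, -np.expm1(-a * np.maximum(x, 0.0)), 0.0),
        sf=lambda x: np.where(x > 0, np.exp(-a * np.maximum(x, 0.0)), 1.0),
        pdf=lambda x: np.where(x >= 0, a * np.exp(-a * np.maximum(x, 0.0)), 0.0),
        logpdf=lambda x: np.where(x >= 0, np.log(a) - a * np.maximum(x, 0.0), -np.inf),
        ppf=lambda u: _edge(lambda v: -np.log1p(-v) / a, u),
    )

    def factory():
        from scipy import stats

        return stats.expon(scale=1.0 / a)

    return BaselineModel(
        name="exponential", params=(("alpha", a),), fns=fns, dist_factory=factory
    )


def make_lomax(alpha: float, beta: float) -> BaselineModel:
    """Lomax baseline with cdf ``1 - (1 + alpha*x)^-beta``.

    ``alpha`` acts as a scale-rate and ``beta`` as the tail index
    (``scipy.stats.lomax(beta, scale=1/alpha)``).
    """
    _require_positive(alpha=alpha, beta=beta)
    a, b = float(alpha), float(beta)
    fns = dict(
        cdf=lambda x: np.where(x > 0, -np.expm1(-b * np.log1p(a * np.maximum(x, 0.0))), 0.0),
        sf=lambda x: np.where(x > 0, np.exp(-b * np.log1p(a * np.maximum(x, 0.0))), 1.0),
        pdf=lambda x: np.where(
            x >= 0, a * b * np.exp(-(b + 1) * np.log1p(a * np.maximum(x, 0.0))), 0.0
        ),
        logpdf=lambda x: np.where(
            x >= 0, np.log(a * b) - (b + 1) * np.log1p(a * np.maximum(x, 0.0)), -np.inf
        ),
        ppf=lambda u: _edge(lambda v: np.expm1(-np.log1p(-v) / b) / a, u),
    )

    def factory():
        from scipy import stats

        return stats.lomax(c=b, scale=1.0 / a)

    return BaselineModel(
        name="lomax", params=(("alpha", a), ("beta", b)), fns=fns, dist_factory=factory
    )


def make_weibull(c: float, lam: float) -> BaselineModel:
    """Weibull baseline with cdf ``1 - exp[-(x/lam)^c]`` (shape ``c``, scale ``lam``)."""
    _require_positive(c=c, lam=lam)
    cc, s = float(c), float(lam)

    def logpdf(x):
        with np.errstate(divide="ignore"):
            xs = np.where(x > 0, x / s, 1.0)
            return np.where(
                x > 0, np.log(cc / s) + (cc - 1) * np.log(xs) - xs**cc, -np.inf
            )

    fns = dict(
        cdf=lambda x: np.where(x > 0, -np.expm1(-((np.maximum(x, 0.0) / s) ** cc)), 0.0),
        sf=lambda x: np.where(x > 0, np.exp(-((np.maximum(x, 0.0) / s) ** cc)), 1.0),
        pdf=lambda x: np.where(x > 0, np.exp(logpdf(x)), 0.0),
        logpdf=logpdf,
        ppf=lambda u: _edge(lambda v: s * (-np.log1p(-v)) ** (1.0 / cc), u),
    )

    def factory():
        from scipy import stats

        return stats.weibull_min(c=cc, scale=s)

    return BaselineModel(
        name="weibull", params=(("c", cc), ("lam", s)), fns=fns, dist_factory=factory
    )


BASELINE_REGISTRY: dict[str, Callable[..., BaselineModel]] = {
    "frechet": make_frechet,
    "exponential": make_exponential,
    "lomax": make_lomax,
    "weibull": make_weibull,
}


def get_baseline(name: str, *params: float) -> BaselineModel:
    """Construct a registered baseline by name with positional parameters."""
    try:
        factory = BASELINE_REGISTRY[name]
    except KeyError:
        known = ", ".join(sorted(BASELINE_REGISTRY))
        raise KeyError(f"unknown baseline {name!r}; available: {known}") from None
    return factory(*params)
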