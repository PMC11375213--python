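"""Gamma-Gompertz(-Makeham) lifespan distributions.

The gamma-Gompertz (GG) family is the workhorse of old-age mortality
modelling: a Gompertz baseline hazard ``a * exp(b*x)`` with a
multiplicative gamma-distributed frailty of variance ``gamma`` yields the
marginal survival function

    S(x) = (1 + (a*gamma/b) * (exp(b*x) - 1)) ** (-1/gamma),

whose hazard rises exponentially through adult ages and levels off at the
plateau ``b/gamma`` at extreme ages.  The Makeham variant multiplies the
survival by ``exp(-c*x)``, adding an age-independent extrinsic hazard
``c``; ``c = 0`` recovers the pure GG law, which is the default
throughout the package because extrinsic mortality is irrelevant at the
supercentenarian ages the record process lives on.

The module provides

* :class:`LifespanLaw` -- the parameter bundle with cdf/pdf/hazard/ppf
  semantics,
* :func:`survival_integral` -- the integral of the survival function,
  in closed form via the Gauss hypergeometric function ``2F1``,
* :class:`MortalityTrend` -- the secular decline of the level parameter,
  ``a_E(t) = K_E * exp(-alpha_E * (t - 2000))``,
* :func:`entry_age_transform` -- conditioning a cohort law on survival
  to a given entry age.

All times are decimal calendar years and all ages decimal years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import integrate, optimize
from scipy.special import hyp2f1

logger = logging.getLogger(__name__)

#: Truncation age for improper integrals over age.  Survival beyond this
#: age is below 1e-12 for every law shipped with the package, so the
#: truncation error is negligible against the quadrature tolerances.
X_MAX = 150.0

#: Adaptive-quadrature tolerances used package-wide.
QUAD_OPTS = {"epsabs": 1e-12, "epsrel": 1e-10, "limit": 200}


def _check_age(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("age must be non-negative")
    return x


@dataclass(frozen=True)
class LifespanLaw:
    """Gamma-Gompertz(-Makeham) lifespan law.

    Parameters
    ----------
    a : float
        Initial mortality level (1/year), ``a > 0``.
    b : float
        Rate of aging, the exponential growth rate of the Gompertz
        hazard (1/year), ``b > 0``.
    gamma : float
        Frailty variance / magnitude of heterogeneity, ``gamma > 0``.
        Controls the deceleration of the hazard; the plateau is
        ``b/gamma``.
    c : float, optional
        Extrinsic (Makeham) mortality (1/year), ``c >= 0``.  The default
        ``c = 0`` selects the pure gamma-Gompertz submodel.
    """

    a: float
    b: float
    gamma: float
    c: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "gamma"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive and finite")
        if not np.isfinite(self.c) or self.c < 0:
            raise ValueError("c must be non-negative and finite")

    # -- core survival machinery -------------------------------------

    def _log_core(self, x: np.ndarray) -> np.ndarray:
        # log(1 + (a*gamma/b)(e^{bx} - 1)), the frailty-mixed Gompertz
        # kernel, written overflow-free for arbitrarily large ages
        r = self.a * self.gamma / self.b
        return self.b * x + np.log(r + (1.0 - r) * np.exp(-self.b * x))

    def sf(self, x):
        """Survival function ``1 - cdf``."""
        with np.errstate(under="ignore"):
            return np.exp(self.logsf(x))

    def cdf(self, x):
        """Cumulative distribution function."""
        return 1.0 - self.sf(x)

    def pdf(self, x):
        """Probability density (1/year)."""
        with np.errstate(under="ignore"):
            return np.exp(self.logpdf(x))

    def hazard(self, x):
        """Force of mortality ``pdf/(1 - cdf)``."""
        x = _check_age(x)
        r = self.a * self.gamma / self.b
        return self.a / (r + (1.0 - r) * np.exp(-self.b * x)) + self.c

    def logsf(self, x):
        x = _check_age(x)
        return -self.c * x - self._log_core(x) / self.gamma

    def logpdf(self, x):
        x = _check_age(x)
        # numerator (c(b-a g) + a(b+c g) e^{bx})/b, factored as
        # e^{bx} * (a(b+c g)/b + c(b-a g)/b e^{-bx}) to stay finite
        lognum = self.b * x + np.log(
            self.a * (self.b + self.c * self.gamma) / self.b
            + self.c * (self.b - self.a * self.gamma) / self.b * np.exp(-self.b * x)
        )
        return -self.c * x - (1.0 + 1.0 / self.gamma) * self._log_core(x) + lognum

    def ppf(self, q):
        """Quantile function.

        Closed form for ``c = 0``; for ``c > 0`` the quantile is found by
        root bracketing on the survival function.
        """
        q = np.asarray(q, dtype=float)
        if np.any((q < 0) | (q > 1)):
            raise ValueError("quantile levels must lie in [0, 1]")
        if self.c == 0.0:
            s = 1.0 - q
            return self.isf_gg(s)
        scalar = q.ndim == 0

        def solve(qi: float) -> float:
            if qi >= 1.0:
                return np.inf
            f = lambda x: self.cdf(x) - qi
            hi = 10.0
            while f(hi) < 0 and hi < 1e4:
                hi *= 2
            return optimize.brentq(f, 0.0, hi, xtol=1e-12)

        out = np.array([solve(float(qi)) for qi in np.atleast_1d(q)])
        return float(out[0]) if scalar else out

    def isf_gg(self, s):
        """Inverse survival function of the GG submodel (``c`` ignored).

        ``x = (1/b) * log(1 + (b/(a*gamma)) * (s^{-gamma} - 1))``.
        """
        s = np.asarray(s, dtype=float)
        with np.errstate(divide="ignore"):
            out = np.log1p(self.b / (self.a * self.gamma) * np.expm1(-self.gamma * np.log(s))) / self.b
        return out

    def mean(self) -> float:
        """Expected lifespan ``int_0^inf S(u) du``."""
        return float(survival_integral(self, 0.0))

    def plateau(self) -> float:
        """Extreme-age hazard limit ``b/gamma + c``."""
        return self.b / self.gamma + self.c

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "gamma": self.gamma, "c": self.c}

    @classmethod
    def from_dict(cls, d: dict) -> "LifespanLaw":
        return cls(a=d["a"], b=d["b"], gamma=d["gamma"], c=d.get("c", 0.0))

    def with_level(self, a: float) -> "LifespanLaw":
        """Same shape parameters, new level ``a``."""
        return replace(self, a=a)


def survival_integral(law: LifespanLaw, x, method: str = "hyp2f1"):
    """Expected remaining exposure ``int_x^inf (1 - F(u)) du`` in years.

    The default path evaluates the closed form

        (b/(a g))^{1/g} * e^{-(c + b/g) x} / (b/g + c)
            * 2F1(1/g, 1/g + c/b; 1 + 1/g + c/b; (a g - b)/(a g) e^{-b x})

    with ``g = gamma``.  At ``x = 0`` this is the expected lifespan.  If
    the hypergeometric evaluation fails to produce a finite value the
    function falls back to adaptive quadrature of the survival function
    (a warning is logged); ``method="quad"`` forces the quadrature path,
    which doubles as the independent oracle in the test-suite.
    """
    x = _check_age(x)
    a, b, g, c = law.a, law.b, law.gamma, law.c
    if method == "hyp2f1":
        z = (a * g - b) / (a * g) * np.exp(-b * x)
        pref = (b / (a * g)) ** (1.0 / g) * np.exp(-(c + b / g) * x) / (b / g + c)
        with np.errstate(over="ignore", invalid="ignore"):
            val = pref * hyp2f1(1.0 / g, 1.0 / g + c / b, 1.0 + 1.0 / g + c / b, z)
        bad = ~np.isfinite(val)
        if not np.any(bad):
            return val if val.ndim else float(val)
        logger.warning(
            "hypergeometric survival integral non-finite for %s at %s; "
            "falling back to adaptive quadrature",
            law,
            x,
        )
        val = np.atleast_1d(val).copy()
        for i in np.nonzero(np.atleast_1d(bad))[0]:
            val[i] = _survival_integral_quad(law, float(np.atleast_1d(x)[i]))
        return val if np.ndim(x) else float(val[0])
    if method == "quad":
        if x.ndim:
            return np.array([_survival_integral_quad(law, float(xi)) for xi in x])
        return _survival_integral_quad(law, float(x))
    raise ValueError(f"unknown method {method!r}")


def _survival_integral_quad(law: LifespanLaw, x: float) -> float:
    # integrate the survival *ratio* S(x+v)/S(x), which is O(1), so the
    # absolute tolerance stays meaningful deep in the tail
    lsx = float(law.logsf(x))
    ratio = lambda v: np.exp(law.logsf(x + v) - lsx)
    val, _ = integrate.quad(ratio, 0.0, np.inf, **QUAD_OPTS)
    with np.errstate(under="ignore"):
        return float(np.exp(lsx) * val)


@dataclass(frozen=True)
class MortalityTrend:
    """Secular trend of the GG level parameter for a fixed entry age.

    The level of mortality at entry (the ``a`` of the GG law governing
    the remaining lifespan of the cohort entering at calendar time
    ``t``) declines exponentially,

        a_E(t) = K * exp(-alpha * (t - 2000)),

    while the shape parameters ``b`` (rate of aging) and ``gamma``
    (heterogeneity) are constant over time.  The year 2000 anchoring is
    purely a normalisation that keeps ``K`` on a readable scale.

    Parameters
    ----------
    K : float
        Mortality level in calendar year 2000 (1/year).
    alpha : float
        Exponential rate of decline (1/year).
    b, gamma : float
        Time-constant GG shape parameters.
    entry_age : float, optional
        Age ``E >= 0`` at which individuals enter the model (default 0,
        i.e. birth).
    c : float, optional
        Makeham term carried through to the laws (default 0).
    """

    K: float
    alpha: float
    b: float
    gamma: float
    entry_age: float = 0.0
    c: float = 0.0

    def __post_init__(self) -> None:
        if self.K <= 0 or self.b <= 0 or self.gamma <= 0:
            raise ValueError("K, b, gamma must all be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative (0 freezes the level in time)")
        if self.entry_age < 0 or self.c < 0:
            raise ValueError("entry_age and c must be non-negative")

    def level(self, t):
        """Mortality level ``a_E(t) = K * exp(-alpha * (t - 2000))``."""
        return self.K * np.exp(-self.alpha * (np.asarray(t, dtype=float) - 2000.0))

    def law_at(self, t: float) -> LifespanLaw:
        """GG law of the remaining lifespan of the cohort entering at ``t``."""
        return LifespanLaw(a=float(self.level(t)), b=self.b, gamma=self.gamma, c=self.c)

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "alpha": self.alpha,
            "b": self.b,
            "gamma": self.gamma,
            "E": self.entry_age,
            "c": self.c,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MortalityTrend":
        return cls(
            K=d["K"],
            alpha=d["alpha"],
            b=d["b"],
            gamma=d["gamma"],
            entry_age=d.get("E", 0.0),
            c=d.get("c", 0.0),
        )


@dataclass(frozen=True)
class ConditionalLaw:
    """Lifespan law conditioned on survival to an entry age.

    For a base cohort law ``F`` and entry age ``E`` the remaining-life
    distribution is

        F^E(x) = (F(x + E) - F(E)) / (1 - F(E)),
        f^E(x) = f(x + E) / (1 - F(E)).
    """

    base: LifespanLaw
    entry_age: float

    def __post_init__(self) -> None:
        if self.entry_age < 0:
            raise ValueError("entry_age must be non-negative")
        if self.base.sf(self.entry_age) < 1e-300:
            raise ValueError(
                "degenerate conditioning: survival to the entry age is numerically zero"
            )

    def sf(self, x):
        x = _check_age(x)
        return self.base.sf(x + self.entry_age) / self.base.sf(self.entry_age)

    def cdf(self, x):
        return 1.0 - self.sf(x)

    def pdf(self, x):
        x = _check_age(x)
        return self.base.pdf(x + self.entry_age) / self.base.sf(self.entry_age)

    def hazard(self, x):
        x = _check_age(x)
        return self.base.hazard(x + self.entry_age)


def entry_age_transform(trend: MortalityTrend, t: float, entry_age: float) -> ConditionalLaw:
    """Remaining-life law at ``entry_age`` for people aged ``entry_age`` at ``t``.

    The cohort was born at ``t - entry_age``; its full-lifespan law is the
    GG law with level ``trend.level(t - entry_age)`` and the returned law
    conditions it on survival to ``entry_age``.  ``entry_age = 0`` is the
    identity transform.
    """
    base = LifespanLaw(
        a=float(trend.level(t - entry_age)), b=trend.b, gamma=trend.gamma, c=trend.c
    )
    return ConditionalLaw(base=base, entry_age=entry_age)


def mortality_level(trend: MortalityTrend, t):
    """Convenience accessor for ``trend.level(t)``."""
    return trend.level(t)
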