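"""Exponential cohort intensity of the birth (entry) process.

The population enters the model as an inhomogeneous Poisson process.  At
entry age ``E`` the rate of people reaching that age at calendar time
``t`` is modelled as a pure exponential,

    lambda_E(t) = C_E * exp(kappa_E * t),

which is the thinned image of the raw birth process: people born at
``t - E`` at rate ``lambda(t - E)`` survive to age ``E`` with probability
``1 - F_{t-E}(E)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import MortalityTrend

_EXP_CAP = 700.0  # exp overflow guard on the log scale


@dataclass(frozen=True)
class BirthIntensity:
    """Exponential entry-age cohort intensity ``C * exp(kappa * t)``.

    Parameters
    ----------
    C : float
        Intensity scale (persons/year), ``C > 0``.
    kappa : float
        Exponential growth rate (1/year).
    entry_age : float, optional
        Entry age the intensity refers to (default 0, i.e. births).
    """

    C: float
    kappa: float
    entry_age: float = 0.0

    def __post_init__(self) -> None:
        if self.C <= 0 or not np.isfinite(self.C):
            raise ValueError("C must be positive and finite")
        if not np.isfinite(self.kappa):
            raise ValueError("kappa must be finite")
        if self.entry_age < 0:
            raise ValueError("entry_age must be non-negative")

    def at(self, t):
        """Rate (persons/year) at calendar time ``t``."""
        t = np.asarray(t, dtype=float)
        if np.any(np.abs(np.log(self.C) + self.kappa * t) > _EXP_CAP):
            raise OverflowError("intensity overflows the double range at this time")
        out = self.C * np.exp(self.kappa * t)
        return out if out.ndim else float(out)

    __call__ = at

    def doubling_time(self) -> float:
        """Time for the rate to double, ``ln 2 / kappa``."""
        return float(np.log(2.0) / self.kappa)

    def to_dict(self) -> dict:
        return {"C": self.C, "kappa": self.kappa, "E": self.entry_age}

    @classmethod
    def from_dict(cls, d: dict) -> "BirthIntensity":
        return cls(C=d["C"], kappa=d["kappa"], entry_age=d.get("E", 0.0))


def thinned_intensity(raw_birth_rate, trend: MortalityTrend, entry_age: float, t):
    """Rate at which people reach ``entry_age`` at time ``t``.

    ``lambda_E(t) = lambda(t - E) * (1 - F_{t-E}(E))`` where the cohort
    law ``F_{t-E}`` is the full-lifespan GG law with level
    ``trend.level(t - E)``.  ``entry_age = 0`` returns the raw rate.

    Parameters
    ----------
    raw_birth_rate : callable
        The raw birth rate ``lambda(t)`` as a function of time.
    trend : MortalityTrend
        Supplies the cohort lifespan law used for the survival thinning.
    entry_age : float
    t : float or ndarray
    """
    if entry_age < 0:
        raise ValueError("entry_age must be non-negative")
    t = np.asarray(t, dtype=float)
    born = t - entry_age
    lam = np.asarray(raw_birth_rate(born), dtype=float)
    if entry_age == 0:
        return lam if lam.ndim else float(lam)
    a = trend.level(born)
    # survival of the cohort law to the entry age, vectorised over t
    core = 1.0 + a * trend.gamma / trend.b * np.expm1(trend.b * entry_age)
    surv = np.exp(-trend.c * entry_age) * core ** (-1.0 / trend.gamma)
    out = lam * surv
    return out if out.ndim else float(out)


def fit_exponential_intensity(counts, entry_age: float = 0.0) -> BirthIntensity:
    """Least-squares exponential fit to cohort counts.

    Ordinary least squares of ``log(count)`` on ``year``; the slope is
    ``kappa`` and ``exp(intercept)`` is ``C``.

    Parameters
    ----------
    counts : sequence of (year, count) pairs, or a 2-column array /
        DataFrame with columns ``year`` and ``count``.

    Returns
    -------
    BirthIntensity
    """
    arr = _as_year_count(counts)
    years, n = arr[:, 0], arr[:, 1]
    if len(years) < 2:
        raise ValueError("at least two (year, count) points are required")
    if np.any(n <= 0):
        raise ValueError("counts must be strictly positive")
    slope, intercept = np.polyfit(years, np.log(n), deg=1)
    return BirthIntensity(C=float(np.exp(intercept)), kappa=float(slope), entry_age=entry_age)


def _as_year_count(counts) -> np.ndarray:
    if hasattr(counts, "columns"):
        cols = {c.lower(): c for c in counts.columns}
        if "year" in cols and "count" in cols:
            return np.column_stack(
                [np.asarray(counts[cols["year"]], float), np.asarray(counts[cols["count"]], float)]
            )
        raise ValueError("DataFrame input needs 'year' and 'count' columns")
    arr = np.asarray(list(counts), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("counts must be (year, count) pairs")
    return arr
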