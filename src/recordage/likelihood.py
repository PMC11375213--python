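"""Titleholder data model and maximum-likelihood fitting.

The data are the transitions of the world's-oldest-person title: triples
``(t_i, y_i, z_i)`` -- the incumbent dies at time ``t_i`` at age ``y_i``
and the successor is ``z_i`` years old at that moment.  Consecutive
triples must agree on the successor's birth date,
``t_i - z_i = t_{i+1} - y_{i+1}`` (the consistency relation).

The log-likelihood of the chain under the entry-age-E record model is

    l(alpha, K, b, gamma) =
        sum_i [ log f^E_{t_i-y_i+E}(y_i - E)
                - int_{z_i}^{y_i} lambda_E(t_i-u+E) (1 - F^E_{t_i-u+E}(u-E)) du ]
        + log(1 - F^E_{t_n-z_n+E}(z_n - E))
        + n log C + kappa sum_i (t_i - z_i + E),

where the survival factors of successive transitions telescope thanks to
the consistency relation.  The last line is parameter-free and omitted
during maximisation (a flag restores it for absolute comparisons).  The
tail integral has a level parameter that depends on the integration
variable, so it is evaluated numerically; the default integrator is a
fixed composite Gauss rule per record (vectorised over the whole
sample), with adaptive quadrature available as a cross-check.

Maximisation uses Nelder-Mead in log-parameter space (positivity for
free) wrapped in a meta-loop that rescales the convergence tolerance
after each run in proportion to the achieved improvement and restarts
from the incumbent optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from ._grid import GaussGrid
from .distributions import MortalityTrend, QUAD_OPTS, X_MAX
from .intensity import BirthIntensity
from .process import RecordAgeProcess

DEGENERATE_K = 1e-10


class ConsistencyError(ValueError):
    """A titleholder chain violates ordering or the consistency relation."""

    def __init__(self, message: str, index: int, residual: float | None = None):
        super().__init__(message)
        self.index = index
        self.residual = residual


class DegenerateFitWarning(UserWarning):
    """The optimizer drifted into a degenerate lifespan law (K < 1e-10).

    Titleholder data only constrain the lifespan law far in its tail, so
    optimising too many shape parameters at once can produce an
    excellent tail fit with essentially no mortality before age 100.
    """


@dataclass(frozen=True)
class TitleholderRecord:
    """One title transition: death time, age at death, successor age."""

    t: float
    y: float
    z: float


def validate_records(records, tol: float = 0.01):
    """Check ordering, 0 < z < y, and the consistency relation.

    Parameters
    ----------
    records : sequence of TitleholderRecord (time-sorted)
    tol : float
        Allowed slack in years on ``t_i - z_i = t_{i+1} - y_{i+1}``
        (day-resolved sources rounded to decimal years need ~1/365).

    Returns
    -------
    The records, unchanged.
    """
    records = list(records)
    for i, r in enumerate(records):
        if not (0.0 < r.z < r.y):
            raise ConsistencyError(
                f"record {i}: need 0 < z < y, got z={r.z}, y={r.y}", index=i
            )
        if i and records[i - 1].t > r.t:
            raise ConsistencyError(f"records not time-sorted at index {i}", index=i)
    for i in range(len(records) - 1):
        lhs = records[i].t - records[i].z
        rhs = records[i + 1].t - records[i + 1].y
        resid = abs(lhs - rhs)
        if resid > tol:
            raise ConsistencyError(
                f"consistency relation violated at index {i + 1}: "
                f"|({records[i].t} - {records[i].z}) - "
                f"({records[i + 1].t} - {records[i + 1].y})| = {resid:.4g} > {tol}",
                index=i + 1,
                residual=resid,
            )
    return records


def record_loglik_term(
    process: RecordAgeProcess, prev_z: float | None, rec: TitleholderRecord
) -> float:
    """Log-likelihood contribution of one transition, by adaptive quadrature.

    ``log f^E`` at the death age, minus the log-survival conditioning at
    the previous successor age (omitted for the first record), plus the
    log jump density at the new successor age.  This is the slow,
    per-record oracle; the model's vectorised log-likelihood telescopes
    to the same sum.
    """
    E = process.entry_age
    if rec.y - E <= 0:
        raise ValueError("death age must exceed the entry age")
    if prev_z is not None and prev_z >= rec.y:
        raise ValueError("previous successor age must be below the death age")
    cohort = rec.t - rec.y + E
    law = process.trend.law_at(cohort)
    term = float(law.logpdf(rec.y - E))
    if prev_z is not None:
        term -= float(law.logsf(prev_z - E))
    term += float(np.log(process.transition_jump_density(rec.t, rec.y, rec.z)))
    return term


@dataclass
class MetaNelderMead:
    """Schedule of the tolerance-rescaling Nelder-Mead meta-loop.

    After each inner run the tolerance shrinks by the ratio of the
    latest improvement to the previous one (clamped), so the optimizer
    tightens only as fast as it keeps paying off.
    """

    tol0: float = 1e-3
    clamp: tuple = (0.1, 1.0)
    stop_improvement: float = 1e-6
    max_meta: int = 12
    maxiter: int | None = None


@dataclass
class TitleholderResults:
    """Maximum-likelihood estimates for a titleholder record chain."""

    model: "TitleholderModel"
    alpha: float
    K: float
    b: float
    gamma: float
    loglik: float
    loglik_full: float
    trace: list
    converged: bool
    degenerate: bool
    free_b: bool = False

    @property
    def params(self) -> dict:
        out = {"alpha": self.alpha, "K": self.K, "gamma": self.gamma}
        if self.free_b:
            out["b"] = self.b
        return out

    @property
    def trend(self) -> MortalityTrend:
        return MortalityTrend(
            K=self.K,
            alpha=self.alpha,
            b=self.b,
            gamma=self.gamma,
            entry_age=self.model.entry_age,
        )

    @property
    def process(self) -> RecordAgeProcess:
        return RecordAgeProcess(intensity=self.model.intensity, trend=self.trend)

    def predict_mean_age(self, years, n_iter: int = 10) -> pd.DataFrame:
        """Fixed-point mean and sd of the record age per calendar year."""
        proc = self.process
        rows = []
        for t in np.asarray(years, dtype=float):
            fp = proc.mean_age_fixed_point(float(t), n_iter=n_iter)
            rows.append({"year": float(t), "mean": fp.mean, "sd": fp.sd})
        return pd.DataFrame(rows)

    def expected_reign_length(self, year: float, freeze: str = "cohort") -> float:
        return self.process.expected_reign_length(year, freeze=freeze)

    def summary(self) -> str:
        lines = [
            "      Titleholder record-age model (gamma-Gompertz trend)",
            "=" * 62,
            f"No. transitions:  {self.model.n_records:>6}     Entry age E:   {self.model.entry_age:g}",
            f"Rate of aging b:  {self.b:.4f}{'' if self.free_b else ' (fixed)'}",
            f"Log-likelihood:   {self.loglik_full:.2f} (with parameter-free terms)",
            f"                  {self.loglik:.2f} (maximised part)",
            f"Meta-iterations:  {len(self.trace):>6}     converged: {self.converged}",
            "-" * 62,
            f"{'parameter':<12}{'estimate':>14}",
            f"{'alpha':<12}{self.alpha:>14.5g}",
            f"{'K':<12}{self.K:>14.5g}",
            f"{'gamma':<12}{self.gamma:>14.5g}",
            "=" * 62,
        ]
        if self.degenerate:
            lines.append("WARNING: degenerate lifespan law (K < 1e-10); see docs.")
        return "\n".join(lines)


class TitleholderModel:
    """Likelihood model for a chain of titleholder transitions.

    Parameters
    ----------
    records : sequence of TitleholderRecord
        Validated, time-sorted transitions.
    entry_age : float
        Entry age ``E`` of the model variant (0, 30 and 60 have packaged
        intensities).
    b : float
        Fixed rate of aging; the default 0.09 is the reference
        calibration.  Use ``fit(free_b=True)`` to optimise it too (and
        expect the documented degeneracy).
    intensity : BirthIntensity, optional
        Entry-age cohort intensity; defaults to the packaged constants
        for the given entry age.
    n_cells, n_nodes : int
        Composite Gauss resolution for each record's tail integral.
    """

    def __init__(
        self,
        records,
        entry_age: float = 0.0,
        b: float = 0.09,
        intensity: BirthIntensity | None = None,
        consistency_tol: float = 0.01,
        n_cells: int = 24,
        n_nodes: int = 6,
        x_max: float = X_MAX,
    ):
        self.records = validate_records(records, tol=consistency_tol)
        self.entry_age = float(entry_age)
        self.b = float(b)
        self.x_max = float(x_max)
        if intensity is None:
            from .tables import BIRTH_INTENSITIES

            try:
                intensity = BIRTH_INTENSITIES[int(entry_age)]
            except KeyError as exc:
                raise ValueError(
                    f"no packaged intensity for entry_age={entry_age}; pass one explicitly"
                ) from exc
        self.intensity = intensity
        E = self.entry_age
        self.t = np.array([r.t for r in self.records])
        self.y = np.array([r.y for r in self.records])
        self.z = np.array([r.z for r in self.records])
        if np.any(self.y - E <= 0):
            raise ValueError("all death ages must exceed the entry age")
        if np.any(self.z - E <= 0):
            raise ValueError("all successor ages must exceed the entry age")
        # per-record Gauss nodes on [z_i, y_i]
        xg, wg = np.polynomial.legendre.leggauss(n_nodes)
        edges = np.linspace(0.0, 1.0, n_cells + 1)
        mid = 0.5 * (edges[:-1] + edges[1:])
        half = 0.5 * np.diff(edges)
        unit_nodes = (mid[:, None] + half[:, None] * xg[None, :]).ravel()
        unit_weights = (half[:, None] * wg[None, :]).ravel()
        span = (self.y - self.z)[:, None]
        self._u = self.z[:, None] + span * unit_nodes[None, :]  # (n, cells*nodes)
        self._w = span * unit_weights[None, :]

    @property
    def n_records(self) -> int:
        return len(self.records)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "TitleholderModel":
        """Build from a frame with columns t/y/z or the CSV schema
        (date_death, age_death_years, successor_age_years)."""
        cols = set(df.columns)
        if {"t", "y", "z"} <= cols:
            recs = [TitleholderRecord(r.t, r.y, r.z) for r in df.itertuples()]
        elif {"date_death", "age_death_years", "successor_age_years"} <= cols:
            recs = [
                TitleholderRecord(
                    float(r.date_death), float(r.age_death_years), float(r.successor_age_years)
                )
                for r in df.itertuples()
            ]
        else:
            raise ValueError("unrecognised titleholder schema")
        return cls(recs, **kwargs)

    # -- log-likelihood ------------------------------------------------

    def _constants(self) -> float:
        E = self.entry_age
        return float(
            self.n_records * np.log(self.intensity.C)
            + self.intensity.kappa * np.sum(self.t - self.z + E)
        )

    def loglik(
        self,
        alpha: float,
        K: float,
        gamma: float,
        b: float | None = None,
        include_constants: bool = False,
        method: str = "gauss",
    ) -> float:
        """Log-likelihood of the chain at the given trend parameters.

        ``method="gauss"`` (default) uses the precomputed vectorised
        composite rule; ``method="quad"`` integrates each record's tail
        term adaptively and exists as the slow cross-check.
        """
        if alpha < 0 or K <= 0 or gamma <= 0:
            raise ValueError("need alpha >= 0, K > 0, gamma > 0")
        b = self.b if b is None else float(b)
        E = self.entry_age
        t, y, z = self.t, self.y, self.z
        C, kappa = self.intensity.C, self.intensity.kappa

        def level(s):
            return K * np.exp(-alpha * (s - 2000.0))

        def log_gg_pdf(a, x):
            core = 1.0 + a * gamma / b * np.expm1(b * x)
            return np.log(a) + b * x - (1.0 + 1.0 / gamma) * np.log(core)

        def gg_sf(a, x):
            core = 1.0 + a * gamma / b * np.expm1(b * x)
            return core ** (-1.0 / gamma)

        a_death = level(t - y + E)
        death_terms = log_gg_pdf(a_death, y - E)

        if method == "gauss":
            s = t[:, None] - self._u + E
            lam = C * np.exp(kappa * s)
            integrals = np.sum(self._w * lam * gg_sf(level(s), self._u - E), axis=1)
        elif method == "quad":
            integrals = np.empty(self.n_records)
            for i in range(self.n_records):
                f = lambda u: (
                    C
                    * np.exp(kappa * (t[i] - u + E))
                    * gg_sf(level(t[i] - u + E), u - E)
                )
                integrals[i], _ = integrate.quad(f, z[i], y[i], epsabs=1e-10, epsrel=1e-10, limit=200)
        else:
            raise ValueError(f"unknown method {method!r}")

        terms = death_terms - integrals
        if not np.all(np.isfinite(terms)):
            bad = int(np.nonzero(~np.isfinite(terms))[0][0])
            raise FloatingPointError(
                f"non-finite log-likelihood contribution at record {bad}"
            )
        tail = float(np.log(gg_sf(level(t[-1] - z[-1] + E), z[-1] - E)))
        out = float(np.sum(terms) + tail)
        if include_constants:
            out += self._constants()
        return out

    # -- fitting --------------------------------------------------------

    def fit(
        self,
        start: tuple = (0.01, 1e-4, 0.1),
        meta: MetaNelderMead | None = None,
        free_b: bool = False,
    ) -> TitleholderResults:
        """Maximise the log-likelihood with the meta-Nelder-Mead loop.

        Parameters
        ----------
        start : tuple
            Initial ``(alpha, K, gamma)`` -- order-of-magnitude guesses
            suffice -- or ``(alpha, K, b, gamma)`` when ``free_b``.
        meta : MetaNelderMead, optional
            Tolerance schedule; defaults are the packaged schedule.
        free_b : bool
            Also optimise the rate of aging.  Documented failure mode:
            the optimum drifts to degenerate laws with K below 1e-10; a
            :class:`DegenerateFitWarning` fires when that happens.
        """
        meta = meta or MetaNelderMead()
        if free_b:
            if len(start) == 3:
                start = (start[0], start[1], self.b, start[2])
            unpack = lambda th: (np.exp(th[0]), np.exp(th[1]), np.exp(th[3]), np.exp(th[2]))
        else:
            if len(start) != 3:
                raise ValueError("start must be (alpha, K, gamma) when b is fixed")
            unpack = lambda th: (np.exp(th[0]), np.exp(th[1]), np.exp(th[2]), None)

        def negloglik(theta):
            alpha, K, gamma, b = unpack(theta)
            try:
                return -self.loglik(alpha, K, gamma, b=b)
            except FloatingPointError:
                return np.inf

        theta = np.log(np.asarray(start, dtype=float))
        best = -negloglik(theta)
        tol = meta.tol0
        trace = []
        prev_improvement = None
        converged = False
        for _ in range(meta.max_meta):
            opts = {"xatol": tol, "fatol": tol}
            if meta.maxiter:
                opts["maxiter"] = meta.maxiter
            res = optimize.minimize(negloglik, theta, method="Nelder-Mead", options=opts)
            improvement = max(-res.fun - best, 0.0)
            if -res.fun >= best:
                best = -res.fun
                theta = res.x
            trace.append((best, tol))
            if improvement < meta.stop_improvement:
                converged = True
                break
            if prev_improvement is not None and prev_improvement > 0:
                ratio = improvement / prev_improvement
                tol *= min(max(ratio, meta.clamp[0]), meta.clamp[1])
            prev_improvement = improvement
        alpha, K, gamma, b = unpack(theta)
        b = self.b if b is None else b
        degenerate = bool(K < DEGENERATE_K)
        if degenerate:
            warnings.warn(
                f"fitted K = {K:.3g} is below {DEGENERATE_K:g}: the lifespan law is "
                "degenerate (almost no mortality before extreme ages); fix more "
                "parameters a priori",
                DegenerateFitWarning,
                stacklevel=2,
            )
        ll = self.loglik(alpha, K, gamma, b=b)
        return TitleholderResults(
            model=self,
            alpha=float(alpha),
            K=float(K),
            b=float(b),
            gamma=float(gamma),
            loglik=ll,
            loglik_full=ll + self._constants(),
            trace=trace,
            converged=converged,
            degenerate=degenerate,
            free_b=free_b,
        )


def sensitivity_scan(
    records,
    entry_ages=(0,),
    bs=(0.09, 0.11, 0.13, 0.15),
    intensities: dict | None = None,
    start: tuple = (0.01, 1e-4, 0.1),
    **model_kwargs,
) -> pd.DataFrame:
    """Grid of fits over entry age and fixed rate of aging.

    Per-cell failures are recorded in the ``error`` column and the scan
    continues.  Output is one row per (E, b) cell with the fitted
    parameters, shaped for CSV export.
    """
    rows = []
    for E in entry_ages:
        for b in bs:
            row = {"E": E, "b": b}
            try:
                intensity = intensities[E] if intensities else None
                model = TitleholderModel(
                    records, entry_age=E, b=b, intensity=intensity, **model_kwargs
                )
                res = model.fit(start=start)
                row.update(
                    alpha=res.alpha,
                    K=res.K,
                    gamma=res.gamma,
                    loglik=res.loglik,
                    loglik_full=res.loglik_full,
                    converged=res.converged,
                    error="",
                )
            except Exception as exc:  # keep scanning
                row.update(
                    alpha=np.nan,
                    K=np.nan,
                    gamma=np.nan,
                    loglik=np.nan,
                    loglik_full=np.nan,
                    converged=False,
                    error=str(exc),
                )
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class BacktestReport:
    """Out-of-sample comparison of a truncated-data fit."""

    results: TitleholderResults
    cutoff: float
    comparison: pd.DataFrame
    n_holdout: int
    n_outside: int


def backtest_split(
    records,
    cutoff: float,
    entry_age: float = 0.0,
    b: float = 0.09,
    intensity: BirthIntensity | None = None,
    start: tuple = (0.01, 1e-4, 0.1),
    **model_kwargs,
) -> BacktestReport:
    """Fit on transitions up to ``cutoff`` and compare with the holdout.

    The comparison evaluates, at each held-out transition time, the
    model's fixed-point mean record age and standard deviation under the
    truncated-data fit, and flags observed death ages outside the
    one-sd band.
    """
    records = list(records)
    train = [r for r in records if r.t <= cutoff]
    holdout = [r for r in records if r.t > cutoff]
    if len(train) < 10:
        raise ValueError(f"only {len(train)} training records before {cutoff}; need >= 10")
    model = TitleholderModel(train, entry_age=entry_age, b=b, intensity=intensity, **model_kwargs)
    res = model.fit(start=start)
    proc = res.process
    rows = []
    for r in holdout:
        fp = proc.mean_age_fixed_point(r.t, n_iter=15)
        rows.append(
            {
                "t": r.t,
                "observed_age_at_death": r.y,
                "predicted_mean": fp.mean,
                "predicted_sd": fp.sd,
                "outside_band": bool(abs(r.y - fp.mean) > fp.sd),
            }
        )
    comparison = pd.DataFrame(
        rows,
        columns=["t", "observed_age_at_death", "predicted_mean", "predicted_sd", "outside_band"],
    )
    n_outside = int(comparison["outside_band"].sum()) if len(rows) else 0
    return BacktestReport(
        results=res,
        cutoff=cutoff,
        comparison=comparison,
        n_holdout=len(holdout),
        n_outside=n_outside,
    )
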