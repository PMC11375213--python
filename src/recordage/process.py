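"""The time-inhomogeneous law of the record holder's age.

With entry-age cohort intensity ``lambda_E`` and remaining-life laws
``F^E_s`` (GG with level ``a_E(s)`` for the cohort entering at time
``s``), the age ``Y_t`` of the oldest person satisfies, for ``x > E``,

    P(Y_t < x) = exp( - int_x^inf lambda_E(t-u+E) (1 - F^E_{t-u+E}(u-E)) du ),

because the people who would be older than ``x`` at time ``t`` form a
Poisson process thinned by survival, and ``{Y_t < x}`` is the event that
this thinned process is empty beyond ``x``.  Differentiation gives the
density, and stopping the tail integral at a death age ``y`` gives the
downward-jump kernel of the Markov process.  Everything here keeps the
full time dependence; the contraction-map approximation that freezes
the mortality level (used for mean-age curves and reign lengths, where
the level inside the tail integral would otherwise depend on the
integration variable) lives in :meth:`RecordAgeProcess.mean_age_fixed_point`
and :meth:`RecordAgeProcess.frozen_homogeneous`.

Ages are actual ages (including the entry age); times are decimal years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

from ._grid import GaussGrid
from .distributions import X_MAX, LifespanLaw, MortalityTrend, QUAD_OPTS
from .homogeneous import HomogeneousModel
from .intensity import BirthIntensity

YEAR_RANGE = (1850.0, 2200.0)  # supported evaluation window for series prediction


@dataclass(frozen=True)
class FixedPointResult:
    """Outcome of the frozen-level mean-age iteration."""

    mean: float
    sd: float
    iterates: tuple
    converged: bool
    frozen_level: float

    def __iter__(self):
        return iter((self.mean, self.sd))


@dataclass
class AgeDistribution:
    """Distribution of the record age at one evaluation time.

    Carries the density on a fine age grid, the atom at 0 (nobody
    alive above the entry age), and a cdf evaluator; moments integrate
    the density with the quadrature rule it was built on.
    """

    t: float
    ages: np.ndarray
    density: np.ndarray
    point_mass: float
    entry_age: float = 0.0
    _log_survivor: np.ndarray = field(default=None, repr=False)
    _nodes: np.ndarray = field(default=None, repr=False)
    _node_weights: np.ndarray = field(default=None, repr=False)
    _node_density: np.ndarray = field(default=None, repr=False)

    def cdf(self, x):
        """``P(Y_t <= x)``; equals the atom below the entry age."""
        x = np.asarray(x, dtype=float)
        G = np.interp(x, self.ages, self._log_survivor)
        with np.errstate(under="ignore"):
            out = np.exp(-G)
        out = np.where(x < self.ages[0], self.point_mass, out)
        return out if out.ndim else float(out)

    def exceedance(self, x):
        return 1.0 - self.cdf(x)

    def total_mass(self) -> float:
        return float(np.sum(self._node_weights * self._node_density) + self.point_mass)

    def moment(self, k: int) -> float:
        """k-th moment of the continuous part (the atom is ignored)."""
        return float(np.sum(self._node_weights * self._nodes**k * self._node_density))

    def mean(self) -> float:
        return self.moment(1)

    def sd(self) -> float:
        m1 = self.moment(1)
        return float(np.sqrt(self.moment(2) - m1 * m1))

    def mode(self) -> float:
        return float(self.ages[int(np.argmax(self.density))])


class RecordAgeProcess:
    """Markov record-age process for one entry-age model.

    Parameters
    ----------
    intensity : BirthIntensity
        Entry-age cohort rate ``lambda_E``.
    trend : MortalityTrend
        Time-varying GG remaining-life law of entering cohorts; must
        share the entry age with ``intensity``.
    x_max : float, optional
        Age truncation for the tail integrals (default 150; survival
        beyond it is < 1e-12 for all shipped calibrations).
    """

    def __init__(self, intensity: BirthIntensity, trend: MortalityTrend, x_max: float = X_MAX):
        if intensity.entry_age != trend.entry_age:
            raise ValueError("intensity and trend must share the entry age")
        self.intensity = intensity
        self.trend = trend
        self.entry_age = float(intensity.entry_age)
        self.x_max = float(x_max)

    # -- thinned exposure rate ----------------------------------------

    def exposure_rate(self, t: float, u):
        """Rate density of people aged exactly ``u`` alive at time ``t``.

        ``lambda_E(t-u+E) * (1 - F^E_{t-u+E}(u-E))`` for ``u >= E``; zero
        below the entry age.  This is the intensity of the age-axis
        Poisson process whose void probabilities give the record-age cdf.
        """
        u = np.asarray(u, dtype=float)
        E = self.entry_age
        entry_time = t - u + E
        lam = self.intensity.at(entry_time)
        a = self.trend.level(entry_time)
        x = np.maximum(u - E, 0.0)
        core = 1.0 + a * self.trend.gamma / self.trend.b * np.expm1(self.trend.b * x)
        with np.errstate(under="ignore"):
            sf = np.exp(-self.trend.c * x) * core ** (-1.0 / self.trend.gamma)
        out = np.where(u >= E, lam * sf, 0.0)
        return out if out.ndim else float(out)

    def _tail_exponent(self, t: float, x: float, upper: float | None = None) -> float:
        upper = self.x_max if upper is None else upper
        if x >= upper:
            return 0.0
        val, _ = integrate.quad(lambda u: self.exposure_rate(t, u), x, upper, **QUAD_OPTS)
        return val

    # -- exact distribution of Y_t ------------------------------------

    def age_cdf(self, t: float, x: float) -> float:
        """``P(Y_t < x)`` for ``x`` above the entry age."""
        if x <= self.entry_age:
            raise ValueError(
                "age_cdf is defined above the entry age; use point_mass for the atom"
            )
        with np.errstate(under="ignore"):
            return float(np.exp(-self._tail_exponent(t, x)))

    def age_density(self, t: float, x: float) -> float:
        """Density of ``Y_t`` at age ``x > E``."""
        if x <= self.entry_age:
            raise ValueError("age_density is defined above the entry age")
        return self.age_cdf(t, x) * self.exposure_rate(t, x)

    def point_mass(self, t: float) -> float:
        """Probability that nobody above the entry age is alive at ``t``."""
        with np.errstate(under="ignore"):
            return float(np.exp(-self._tail_exponent(t, self.entry_age)))

    def exceedance_probability(self, t: float, x: float) -> float:
        """``P(Y_t >= x)``, the chance the record age reaches ``x`` at ``t``."""
        return 1.0 - self.age_cdf(t, x)

    # -- transition kernel --------------------------------------------

    def transition_jump_density(self, t: float, y: float, x: float) -> float:
        """Density of the successor's age, given a death at age ``y`` at ``t``.

        Zero below the entry age; the atom (record resets) is
        :meth:`transition_point_mass`.
        """
        if x >= y:
            raise ValueError("successor age must satisfy x < y")
        if x <= self.entry_age:
            return 0.0
        with np.errstate(under="ignore"):
            return float(
                np.exp(-self._tail_exponent(t, x, upper=y)) * self.exposure_rate(t, x)
            )

    def transition_point_mass(self, t: float, y: float) -> float:
        """Probability the record drops to the atom at a death at age ``y``."""
        if y <= self.entry_age:
            return 1.0
        with np.errstate(under="ignore"):
            return float(np.exp(-self._tail_exponent(t, self.entry_age, upper=y)))

    def sample_transition(self, t: float, y: float, size: int, rng) -> np.ndarray:
        """Inverse-cdf draws of the successor age after a death at ``(y, t)``.

        Returns 0.0 for draws that land in the reset atom.
        """
        grid = GaussGrid(self.entry_age, y, n_cells=max(400, int((y - self.entry_age) * 40)))
        g = self.exposure_rate(t, grid.flat_nodes)
        tail = grid.tail_integrals(g)  # int_edge^y
        with np.errstate(under="ignore"):
            cdf_edges = np.exp(-tail)
        u = rng.uniform(size=size)
        out = np.interp(u, cdf_edges, grid.edges)
        out[u < cdf_edges[0]] = 0.0
        return out

    # -- grid evaluation -----------------------------------------------

    def age_distribution(self, t: float, grid_step: float = 0.05) -> AgeDistribution:
        """Full distribution of ``Y_t`` on an age grid of the given step."""
        E = self.entry_age
        n_cells = max(64, int(np.ceil((self.x_max - E) / grid_step)))
        grid = GaussGrid(E, self.x_max, n_cells)
        g_nodes = self.exposure_rate(t, grid.flat_nodes)
        tail_edges = grid.tail_integrals(g_nodes)

        # exact log-survivor at interior nodes: tail from the cell's right
        # edge plus a nested 4-point rule from the node to that edge
        sub = GaussGrid(0.0, 1.0, 1, 4)
        frac, wsub = sub.flat_nodes, sub.flat_weights
        nodes = grid.nodes  # (cells, 6)
        right = grid.edges[1:][:, None]
        span = right - nodes
        subnodes = nodes[..., None] + span[..., None] * frac  # (cells, 6, 4)
        g_sub = self.exposure_rate(t, subnodes.ravel()).reshape(subnodes.shape)
        inner = np.sum(g_sub * wsub, axis=-1) * span
        G_nodes = tail_edges[1:][:, None] + inner

        with np.errstate(under="ignore"):
            h_nodes = np.exp(-G_nodes.ravel()) * g_nodes
            g_edges = self.exposure_rate(t, grid.edges)
            h_edges = np.exp(-tail_edges) * g_edges
            m = float(np.exp(-tail_edges[0]))
        return AgeDistribution(
            t=t,
            ages=grid.edges,
            density=h_edges,
            point_mass=m,
            entry_age=E,
            _log_survivor=tail_edges,
            _nodes=grid.flat_nodes,
            _node_weights=grid.flat_weights,
            _node_density=h_nodes,
        )

    def predict_age_density_series(self, years, grid_step: float = 0.05) -> list:
        """Exact (fully time-dependent) age distributions for several years."""
        years = np.asarray(years, dtype=float)
        if np.any((years < YEAR_RANGE[0]) | (years > YEAR_RANGE[1])):
            raise ValueError(f"years must lie within {YEAR_RANGE}")
        return [self.age_distribution(float(t), grid_step=grid_step) for t in years]

    # -- frozen-level approximation -----------------------------------

    def _frozen_moments(self, t: float, d: float, grid_step: float = 0.1):
        """(mean, sd, mass) of the age density with the level frozen at a_E(t-d)."""
        E = self.entry_age
        a0 = float(self.trend.level(t - d))
        law = LifespanLaw(a=a0, b=self.trend.b, gamma=self.trend.gamma, c=self.trend.c)
        n_cells = max(64, int(np.ceil((self.x_max - E) / grid_step)))
        grid = GaussGrid(E, self.x_max, n_cells)
        u = grid.flat_nodes
        g = self.intensity.at(t - u + E) * law.sf(u - E)
        tail = grid.tail_integrals(g)
        # log-survivor at nodes via the same nested rule as age_distribution
        sub = GaussGrid(0.0, 1.0, 1, 4)
        frac, wsub = sub.flat_nodes, sub.flat_weights
        right = grid.edges[1:][:, None]
        span = right - grid.nodes
        subnodes = grid.nodes[..., None] + span[..., None] * frac
        su = subnodes.ravel()
        g_sub = (self.intensity.at(t - su + E) * law.sf(np.maximum(su - E, 0.0))).reshape(
            subnodes.shape
        )
        G_nodes = tail[1:][:, None] + np.sum(g_sub * wsub, axis=-1) * span
        with np.errstate(under="ignore"):
            h = np.exp(-G_nodes.ravel()) * g
        w = grid.flat_weights
        mass = float(np.sum(w * h))
        m1 = float(np.sum(w * u * h))
        m2 = float(np.sum(w * u * u * h))
        return m1, float(np.sqrt(m2 - m1 * m1)), mass

    def mean_age_fixed_point(
        self,
        t: float,
        n_iter: int = 10,
        d0: float = 100.0,
        tol: float = 1e-6,
        grid_step: float = 0.1,
    ) -> FixedPointResult:
        """Mean record age via the frozen-level contraction map.

        The level inside the tail integral depends on the integration
        variable, so the exact mean has no closed form; freezing the
        level at ``a_E(t - d)`` and iterating ``d -> mean age under the
        frozen density`` converges in a few steps because the age
        distribution is highly concentrated.  The standard deviation is
        computed under the same frozen density at the fixed point.
        """
        if n_iter < 1:
            raise ValueError("n_iter must be at least 1")
        d = float(d0)
        iterates = []
        sd = np.nan
        for _ in range(n_iter):
            mean, sd, _ = self._frozen_moments(t, d, grid_step=grid_step)
            iterates.append(mean)
            delta = abs(mean - d)
            d = mean
            if delta <= tol:
                break
        converged = len(iterates) > 1 and abs(iterates[-1] - iterates[-2]) <= tol
        if not converged and len(iterates) == n_iter:
            final_step = abs(iterates[-1] - iterates[-2]) if len(iterates) > 1 else np.inf
            if final_step > tol:
                warnings.warn(
                    f"fixed-point iteration did not reach |delta| <= {tol} after "
                    f"{n_iter} iterations (last step {final_step:.2e}); returning last iterate",
                    RuntimeWarning,
                    stacklevel=2,
                )
        return FixedPointResult(
            mean=d,
            sd=float(sd),
            iterates=tuple(iterates),
            converged=converged or (len(iterates) < n_iter),
            frozen_level=float(self.trend.level(t - d)),
        )

    def frozen_homogeneous(
        self, t: float, freeze: str = "cohort", n_iter: int = 10
    ) -> tuple[HomogeneousModel, FixedPointResult]:
        """Homogeneous model frozen at the mean-age fixed point for year ``t``.

        ``freeze="cohort"`` (default) evaluates both the intensity and
        the mortality level at the cohort time ``t - d*`` experienced by
        the typical record holder, matching the frozen-cohort logic of
        the contraction map; ``freeze="current"`` uses time ``t`` itself.
        """
        fp = self.mean_age_fixed_point(t, n_iter=n_iter)
        if freeze == "cohort":
            s = t - fp.mean
        elif freeze == "current":
            s = t
        else:
            raise ValueError("freeze must be 'cohort' or 'current'")
        law = LifespanLaw(
            a=float(self.trend.level(s)), b=self.trend.b, gamma=self.trend.gamma, c=self.trend.c
        )
        hom = HomogeneousModel(lam=float(self.intensity.at(s)), law=law, x_max=self.x_max)
        return hom, fp

    def expected_reign_length(self, t: float, freeze: str = "cohort", n_iter: int = 10) -> float:
        """Mean reign length of the record holder around year ``t``."""
        hom, _ = self.frozen_homogeneous(t, freeze=freeze, n_iter=n_iter)
        return hom.expected_reign_length()
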