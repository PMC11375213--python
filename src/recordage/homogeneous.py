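"""Stationary theory of the record-age process with constant rates.

When individuals are born at a constant Poisson rate ``lam`` and share a
single time-constant lifespan law ``F``, the age ``Y`` of the oldest
person is a stationary Markov process and everything of interest has a
closed form in terms of the tail integral of the survival function
``S1(x) = int_x^inf (1 - F(u)) du``:

* the stationary age density ``h(x) = exp(-lam*S1(x)) * lam * (1-F(x))``
  with an atom ``m = exp(-lam * E[lifespan])`` at 0,
* the downward-jump law at a death at age ``y`` with density
  ``j_y(x) = exp(-lam * int_x^y (1-F)) * lam * (1-F(x))`` and atom
  ``a_y`` at 0,
* the stationary density of ages at death of record holders (the
  "peaks" chain) ``z(x) propto f(x) * exp(-lam*S1(x))``,
* the reign-length density ``r(w)`` and its mean.

These formulas also serve as oracles for the general time-inhomogeneous
process, which reduces to this model when the intensity and the law are
frozen.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate

from ._grid import GaussGrid
from .distributions import X_MAX, LifespanLaw, QUAD_OPTS, survival_integral


class HomogeneousModel:
    """Record-age model with constant birth rate and fixed lifespan law.

    Parameters
    ----------
    lam : float
        Constant birth rate (persons/year), ``lam > 0``.
    law : LifespanLaw
        Time-constant lifespan distribution.
    x_max : float, optional
        Age truncation for numerical integrals (default 150).
    n_cells, n_nodes : int, optional
        Resolution of the composite Gauss grid backing grid-based
        evaluations (cdf caches, reign-length integrals).
    """

    def __init__(
        self,
        lam: float,
        law: LifespanLaw,
        x_max: float = X_MAX,
        n_cells: int = 1500,
        n_nodes: int = 6,
    ):
        if lam <= 0 or not np.isfinite(lam):
            raise ValueError("lam must be positive and finite")
        self.lam = float(lam)
        self.law = law
        self.x_max = float(x_max)
        self._grid = GaussGrid(0.0, self.x_max, n_cells, n_nodes)
        self._cache: dict = {}

    # -- survival machinery -------------------------------------------

    def survival_tail(self, x):
        """``S1(x) = int_x^inf (1 - F(u)) du``."""
        if isinstance(self.law, LifespanLaw):
            return survival_integral(self.law, x)
        x = np.asarray(x, dtype=float)
        if x.ndim:
            return np.array([self._s1_quad(float(xi)) for xi in x])
        return self._s1_quad(float(x))

    def _s1_quad(self, x: float) -> float:
        val, _ = integrate.quad(self.law.sf, x, np.inf, **QUAD_OPTS)
        return val

    def expected_lifespan(self) -> float:
        return float(self.survival_tail(0.0))

    # -- stationary age distribution ----------------------------------

    def stationary_density(self, x):
        """Density ``h`` of the stationary record age on ``(0, inf)``."""
        x = np.asarray(x, dtype=float)
        with np.errstate(under="ignore"):
            out = np.exp(-self.lam * self.survival_tail(x)) * self.lam * self.law.sf(x)
        return out if out.ndim else float(out)

    def point_mass(self) -> float:
        """Atom of the stationary law at age 0, ``exp(-lam*E[lifespan])``."""
        with np.errstate(under="ignore"):
            return float(np.exp(-self.lam * self.expected_lifespan()))

    def stationary_cdf(self, x):
        """``P(Y <= x) = exp(-lam * S1(x))`` (includes the atom at 0)."""
        with np.errstate(under="ignore"):
            out = np.exp(-self.lam * self.survival_tail(x))
        return out

    # -- jump law at a death ------------------------------------------

    def jump_density(self, y: float, x):
        """Density of the successor age, given a death at age ``y``."""
        x = np.asarray(x, dtype=float)
        if np.any(x >= y):
            raise ValueError("jump destination must satisfy x < y")
        with np.errstate(under="ignore"):
            expo = self.lam * (self.survival_tail(x) - self.survival_tail(y))
            out = np.exp(-expo) * self.lam * self.law.sf(x)
        return out if out.ndim else float(out)

    def jump_point_mass(self, y: float) -> float:
        """Probability that the record drops to 0 at a death at age ``y``."""
        with np.errstate(under="ignore"):
            return float(
                np.exp(-self.lam * (self.survival_tail(0.0) - self.survival_tail(y)))
            )

    # -- peaks process -------------------------------------------------

    def _peaks_normalizer(self) -> float:
        if "zn" not in self._cache:
            xs = self._grid.flat_nodes
            with np.errstate(under="ignore"):
                vals = self.law.pdf(xs) * np.exp(-self.lam * self.survival_tail(xs))
            self._cache["zn"] = self._grid.integral(vals)
        return self._cache["zn"]

    def peaks_density(self, x):
        """Stationary density of record holders' ages at death."""
        x = np.asarray(x, dtype=float)
        with np.errstate(under="ignore"):
            out = (
                self.law.pdf(x)
                * np.exp(-self.lam * self.survival_tail(x))
                / self._peaks_normalizer()
            )
        return out if out.ndim else float(out)

    def peaks_cdf(self, x):
        """cdf of the peaks density, from the cached grid."""
        if "zcdf" not in self._cache:
            xs = self._grid.flat_nodes
            vals = self.peaks_density(xs)
            tail = self._grid.tail_integrals(vals)
            total = tail[0]
            self._cache["zcdf"] = (self._grid.edges, total - tail)
        edges, cum = self._cache["zcdf"]
        return np.interp(np.asarray(x, dtype=float), edges, cum, left=0.0, right=1.0)

    # -- reign length ---------------------------------------------------

    def _h_support(self):
        """Grid nodes restricted to where the stationary density matters.

        Mass below 1e-18 of the peak contributes nothing at the package
        tolerances but dominates the cost of reign-length integrals when
        the birth rate is large and the density very concentrated.
        """
        if "hsup" not in self._cache:
            ys = self._grid.flat_nodes
            wts = self._grid.flat_weights
            hv = self.stationary_density(ys)
            keep = hv > hv.max() * 1e-18
            self._cache["hsup"] = (ys[keep], wts[keep], hv[keep])
        return self._cache["hsup"]

    def _den(self) -> float:
        if "den" not in self._cache:
            xs = self._grid.flat_nodes
            hv = self.stationary_density(xs)
            self._cache["den"] = self._grid.integral(hv * self.law.sf(xs)) + self.point_mass()
        return self._cache["den"]

    def reign_length_density(self, w):
        """Density ``r`` of the reign length of a record holder.

        ``r(w) = [int h(y) f(y+w) dy + m * (f * Exp(lam))(w)] / D`` with
        ``D = int h(y)(1-F(y)) dy + m``; the convolution term only
        matters when the atom ``m`` is non-negligible (small
        populations).
        """
        w = np.asarray(w, dtype=float)
        if np.any(w < 0):
            raise ValueError("reign length must be non-negative")
        scalar = w.ndim == 0
        w1 = np.atleast_1d(w)
        ys, wts, hv = self._h_support()
        # int h(y) f(y+w) dy, vectorised over w in manageable chunks
        num = np.empty_like(w1)
        chunk = max(1, int(2e6 / ys.size))
        for i in range(0, w1.size, chunk):
            blk = w1[i : i + chunk]
            num[i : i + chunk] = np.sum(
                (wts * hv)[None, :] * self.law.pdf(ys[None, :] + blk[:, None]), axis=1
            )
        m = self.point_mass()
        if m > 1e-14 * self._den():  # atom contributes above round-off
            num = num + m * self._exp_convolution(w1)
        out = num / self._den()
        return float(out[0]) if scalar else out

    def _exp_convolution(self, w: np.ndarray) -> np.ndarray:
        # density of lifespan + Exp(lam) at w
        out = np.empty_like(w)
        for i, wi in enumerate(w):
            if wi == 0.0:
                out[i] = 0.0
                continue
            f = lambda z: self.law.pdf(z) * self.lam * np.exp(-self.lam * (wi - z))
            out[i], _ = integrate.quad(f, 0.0, wi, **QUAD_OPTS)
        return out

    def reign_length_cdf(self, w, w_max: float | None = None, n_cells: int = 800):
        """cdf of the reign length via a cached cumulative grid."""
        key = ("rcdf", w_max, n_cells)
        if key not in self._cache:
            if w_max is None:
                w_max = self.x_max
            g = GaussGrid(0.0, w_max, n_cells, 6)
            vals = self.reign_length_density(g.flat_nodes)
            tail = g.tail_integrals(vals)
            self._cache[key] = (g.edges, tail[0] - tail)
        edges, cum = self._cache[key]
        return np.interp(np.asarray(w, dtype=float), edges, cum, left=0.0, right=1.0)

    def expected_reign_length(self) -> float:
        """Mean reign length ``int w r(w) dw``.

        Uses ``int_0^inf w f(y+w) dw = S1(y)`` (integration by parts), so
        the numerator collapses to ``int h(y) S1(y) dy`` plus the atom
        contribution ``m * (E[lifespan] + 1/lam)``.
        """
        ys = self._grid.flat_nodes
        hv = self.stationary_density(ys)
        s1 = self.survival_tail(ys)
        num = self._grid.integral(hv * s1)
        m = self.point_mass()
        if m > 1e-14 * self._den():
            num += m * (self.expected_lifespan() + 1.0 / self.lam)
        return float(num / self._den())
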