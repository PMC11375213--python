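"""Piecewise Gauss-Legendre quadrature grids.

Shared by the stationary and time-inhomogeneous record-age computations:
integrands are smooth but can vary on sub-year scales when the birth
rate is large, so fixed composite Gauss rules on fine cells give
near-machine accuracy at predictable cost, and cellwise integrals can be
accumulated from the right to evaluate tail integrals on a whole grid at
once.
"""

from __future__ import annotations

import numpy as np


class GaussGrid:
    """Composite Gauss-Legendre rule on ``n_cells`` equal cells of [lo, hi]."""

    def __init__(self, lo: float, hi: float, n_cells: int, n_nodes: int = 6):
        if hi <= lo:
            raise ValueError("need hi > lo")
        self.edges = np.linspace(lo, hi, n_cells + 1)
        xg, wg = np.polynomial.legendre.leggauss(n_nodes)
        mid = 0.5 * (self.edges[:-1] + self.edges[1:])
        half = 0.5 * np.diff(self.edges)
        #: nodes and weights, shape (n_cells, n_nodes)
        self.nodes = mid[:, None] + half[:, None] * xg[None, :]
        self.weights = half[:, None] * wg[None, :]

    @property
    def flat_nodes(self) -> np.ndarray:
        return self.nodes.ravel()

    @property
    def flat_weights(self) -> np.ndarray:
        return self.weights.ravel()

    def integral(self, values: np.ndarray) -> float:
        """Integral over [lo, hi] of a function sampled on ``flat_nodes``."""
        return float(np.sum(self.flat_weights * values))

    def tail_integrals(self, values: np.ndarray) -> np.ndarray:
        """``int_{edge_k}^{hi}`` for every cell edge, from node samples.

        Returns an array aligned with ``edges`` (last entry is 0).
        """
        cell = np.sum(self.weights * values.reshape(self.nodes.shape), axis=1)
        tail = np.concatenate([np.cumsum(cell[::-1])[::-1], [0.0]])
        return tail
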