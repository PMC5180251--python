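"""Differential quadrature machinery: collocation nodes and weighting matrices.

The differential quadrature method (DQM) approximates the derivative of a
field at a collocation node as a weighted sum of the field values at all
nodes; the weights are exact for the Lagrange interpolating polynomial
through the nodes.  Grids are small (tens of points per direction) and the
matrices are stored dense.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DQMGrid", "cgl_nodes", "uniform_nodes", "weighting_matrix", "make_grid"]


def cgl_nodes(n: int) -> np.ndarray:
    """Chebyshev–Gauss–Lobatto nodes on [0, 1]: ``(1 - cos(i pi/(n-1)))/2``.

    Endpoint-clustered sampling, the standard stable choice for DQM.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    i = np.arange(n)
    return (1.0 - np.cos(i * np.pi / (n - 1))) / 2.0


def uniform_nodes(n: int) -> np.ndarray:
    if n < 2:
        raise ValueError("need at least 2 nodes")
    return np.linspace(0.0, 1.0, n)


def weighting_matrix(nodes: np.ndarray, order: int = 1, d2_mode: str = "recurrence") -> np.ndarray:
    """Derivative weighting matrix on arbitrary distinct nodes.

    First-order weights use the Lagrange product formula
    ``D1_ij = M'(x_i) / ((x_i - x_j) M'(x_j))`` for i != j with diagonal
    entries from the negative row sum (a constant has zero derivative).
    Second-order weights use the standard recurrence
    ``D2_ij = 2 (D1_ij D1_ii - D1_ij / (x_i - x_j))`` off-diagonal
    (``d2_mode="recurrence"``, default) or the square ``D1 @ D1``
    (``d2_mode="square"``).
    """
    x = np.asarray(nodes, dtype=float)
    n = x.size
    diff = x[:, None] - x[None, :]
    if np.any(np.abs(diff + np.eye(n)) < 1e-15 * max(1.0, np.max(np.abs(x)))):
        raise ValueError("collocation nodes must be distinct")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")

    # M'(x_i) = prod_{j != i} (x_i - x_j)
    np.fill_diagonal(diff, 1.0)
    Mp = np.prod(diff, axis=1)
    np.fill_diagonal(diff, np.inf)

    D1 = (Mp[:, None] / Mp[None, :]) / diff
    np.fill_diagonal(D1, 0.0)
    np.fill_diagonal(D1, -D1.sum(axis=1))
    if order == 1:
        return D1

    if d2_mode == "square":
        return D1 @ D1
    D2 = 2.0 * (D1 * np.diag(D1)[:, None] - D1 / diff)
    np.fill_diagonal(D2, 0.0)
    np.fill_diagonal(D2, -D2.sum(axis=1))
    return D2


@dataclass(frozen=True)
class DQMGrid:
    """Collocation grid on [0, 1] with first- and second-derivative matrices."""

    n_points: int
    nodes: np.ndarray
    D1: np.ndarray
    D2: np.ndarray

    def scaled(self, a: float, b: float) -> "DQMGrid":
        """Map the grid to the physical interval [a, b]."""
        h = b - a
        if h <= 0:
            raise ValueError("interval must have positive length")
        return DQMGrid(self.n_points, a + h * self.nodes, self.D1 / h, self.D2 / h**2)


def make_grid(n: int, family: str = "cgl", d2_mode: str = "recurrence") -> DQMGrid:
    if family not in ("cgl", "uniform"):
        raise ValueError(f"unknown grid family {family!r}")
    nodes = cgl_nodes(n) if family == "cgl" else uniform_nodes(n)
    return DQMGrid(n, nodes, weighting_matrix(nodes, 1), weighting_matrix(nodes, 2, d2_mode))
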