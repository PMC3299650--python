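"""Quadratic smoothness penalty on the pixel grid.

``x^T Q x = sum over 4-neighbour pairs (x_i - x_j)^2`` — the graph Laplacian
of the grid.  The pure Laplacian is singular (constant images cost nothing),
so wherever an inverse is required (the initial covariance of the state-space
recursion is ``P(0) = Q^{-1}``) a small ridge ``rho * I`` with
``rho = 1e-6 * trace(Q) / n`` is added.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .geometry import ScanGeometry

__all__ = ["PenaltyModel", "grid_laplacian"]


def grid_laplacian(geom: ScanGeometry) -> sp.csr_matrix:
    """Sparse 4-neighbour graph Laplacian of the image grid."""
    nx, ny = geom.grid_nx, geom.grid_ny
    idx = np.arange(ny * nx).reshape(ny, nx)
    pairs = []
    if nx > 1:
        pairs.append((idx[:, :-1].ravel(), idx[:, 1:].ravel()))
    if ny > 1:
        pairs.append((idx[:-1, :].ravel(), idx[1:, :].ravel()))
    if not pairs:
        return sp.csr_matrix((1, 1))
    rows = np.concatenate([p[0] for p in pairs])
    cols = np.concatenate([p[1] for p in pairs])
    n = nx * ny
    ones = np.ones(rows.size)
    adj = sp.coo_matrix((ones, (rows, cols)), shape=(n, n))
    adj = (adj + adj.T).tocsr()
    degree = np.asarray(adj.sum(axis=1)).ravel()
    return (sp.diags(degree) - adj).tocsr()


@dataclass
class PenaltyModel:
    """Smoothness penalty ``beta * x^T Q x`` with a 4-neighbour Laplacian Q."""

    geometry: ScanGeometry
    beta: float = 1.0
    ridge_scale: float = 1e-6
    Q: sp.csr_matrix = field(init=False)

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        self.Q = grid_laplacian(self.geometry)

    @property
    def ridge(self) -> float:
        n = self.Q.shape[0]
        return self.ridge_scale * float(self.Q.diagonal().sum()) / n

    def ridged(self) -> sp.csr_matrix:
        """Invertible ``Q + rho I`` used where ``Q^{-1}`` is needed."""
        return (self.Q + self.ridge * sp.identity(self.Q.shape[0])).tocsr()

    def quad(self, x: np.ndarray) -> float:
        """The roughness ``x^T Q x`` (no beta factor)."""
        return float(x @ (self.Q @ x))
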