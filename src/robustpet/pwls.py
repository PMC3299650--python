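"""Penalized weighted least squares solved by linear conjugate gradients.

Minimizes ``(y - Dx)^T W (y - Dx) + beta * x^T Q x`` with a diagonal
weighting ``W`` (typically the inverse plug-in Poisson variance) and the
quadratic smoothness penalty ``Q``.  The normal equations

    (D^T W D + beta Q) x = D^T W y

are solved matrix-free by conjugate gradients, so no dense system is ever
formed; the quadratic objective is nonincreasing along CG iterations.
Negative corrected bins are used as-is; the final image is clipped to zero
only on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import normalized_error
from .geometry import ActivityImage, Sinogram
from .penalty import PenaltyModel
from .projector import SystemMatrix

__all__ = ["PWLSResult", "pwls_cg_reconstruct", "default_beta"]


@dataclass
class PWLSResult:
    image: ActivityImage
    objective: list[float] = field(default_factory=list)
    error_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    grad_norm: float = float("nan")


def _as_weight_vector(W, m: int) -> np.ndarray:
    w = np.asarray(W, dtype=float)
    if w.ndim == 0:
        w = np.full(m, float(w))
    if w.shape != (m,):
        raise ValueError("W must be a scalar or a length-m diagonal vector")
    if np.any(w <= 0):
        raise ValueError("W must be positive definite")
    return w


def default_beta(D: SystemMatrix, W, penalty: PenaltyModel) -> float:
    """Scale-aware default smoothing weight.

    Balances the data and penalty curvatures through their traces,
    ``tr(D^T W D) / tr(Q)``, damped by 2^-4 so smoothing stays mild.
    """
    w = _as_weight_vector(W, D.geometry.n_rays)
    sq_row_sums = np.asarray(D.entries.multiply(D.entries).sum(axis=1)).ravel()
    data_trace = float(w @ sq_row_sums)
    q_trace = float(penalty.Q.diagonal().sum())
    if q_trace <= 0:
        return 0.0
    return 2.0 ** -4 * data_trace / q_trace


def pwls_cg_reconstruct(
    y: Sinogram,
    D: SystemMatrix,
    W,
    penalty: PenaltyModel,
    n_iter: int = 100,
    x0: ActivityImage | None = None,
    x_true: ActivityImage | None = None,
    epsilon: float | None = None,
    tol: float = 1e-10,
) -> PWLSResult:
    """Conjugate-gradient minimization of the PWLS objective."""
    if y.geometry != D.geometry:
        raise ValueError("sinogram geometry does not match system matrix")
    m, n = D.entries.shape
    w = _as_weight_vector(W, m)
    beta = penalty.beta
    Dm = D.entries

    def apply_A(v: np.ndarray) -> np.ndarray:
        out = Dm.T @ (w * (Dm @ v))
        if beta > 0:
            out = out + beta * (penalty.Q @ v)
        return out

    def objective(v: np.ndarray) -> float:
        r = y.values - Dm @ v
        return float(r @ (w * r) + beta * penalty.quad(v))

    b = Dm.T @ (w * y.values)
    x = np.zeros(n) if x0 is None else x0.values.copy()
    r = b - apply_A(x)
    p = r.copy()
    rs = float(r @ r)
    rs0 = rs
    result = PWLSResult(image=ActivityImage(D.geometry, np.maximum(x, 0)))
    prev_err = None
    for k in range(n_iter):
        if rs <= tol * max(rs0, 1e-300):
            break
        Ap = apply_A(p)
        denom = float(p @ Ap)
        if denom <= 0:
            break
        alpha = rs / denom
        x = x + alpha * p
        r = r - alpha * Ap
        rs_new = float(r @ r)
        p = r + (rs_new / rs) * p
        rs = rs_new
        result.objective.append(objective(x))
        result.n_iter = k + 1
        if x_true is not None:
            err = normalized_error(ActivityImage(D.geometry, np.maximum(x, 0)), x_true)
            result.error_trace.append(err)
            if epsilon is not None and prev_err is not None and abs(err - prev_err) <= epsilon:
                break
            prev_err = err
    result.grad_norm = float(np.linalg.norm(apply_A(x) - b))
    result.image = ActivityImage(D.geometry, np.maximum(x, 0))
    return result
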