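"""Regularized robust least squares under norm-bounded uncertainty.

The core estimation problem is the min-max program

    min_x  max_{||Delta|| <= phi}  x^T Q x + ||(A + Mf Delta Ef) x - (b + Mf Delta Eg)||^2_W

whose inner maximum is over an arbitrary contraction ``Delta`` entering the
data matrix and vector through the fixed structure ``(Mf, Ef, Eg)``.  The
unique minimizer has the closed form of a *corrected* regularized weighted
least squares problem:

    x = (Q_hat + A^T W_hat A)^{-1} (A^T W_hat b + lam * Ef^T Eg)

with

    Q_hat = Q + lam * Ef^T Ef
    W_hat = W + W Mf (lam I - Mf^T W Mf)^+ Mf^T W

where ``lam`` is a scalar regularization parameter that must satisfy
``lam >= lambda_lower = ||Mf^T W Mf||`` for ``W_hat`` to be well defined
(``+`` denotes the Moore-Penrose pseudo-inverse, used when the bracket is
singular).  The optimal ``lam`` minimizes a scalar cost ``G(lam)`` — the
robust objective evaluated at the lam-parameterized solution — over
``(lambda_lower, inf)``; a cheap and common shortcut sets
``lam = (1 + alpha) * lambda_lower`` instead.  ``phi`` is absorbed by
rescaling ``Ef`` and ``Eg``.

Setting ``Mf = 0`` (accurate model) collapses everything to ordinary
regularized weighted least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.optimize import minimize_scalar
from scipy.sparse.linalg import gmres, spilu, LinearOperator

from .uncertainty import UncertaintyModel

__all__ = [
    "RobustSolveParams",
    "RobustSolution",
    "lambda_lower_bound",
    "corrected_weight",
    "robust_ls_solve",
    "select_lambda",
]

#: problems up to this many unknowns are solved densely (Cholesky); larger
#: ones fall back to a preconditioned Krylov iteration
DENSE_LIMIT = 4600


@dataclass(frozen=True)
class RobustSolveParams:
    """How the regularization scalar ``lam`` is chosen.

    ``alpha_shortcut`` sets ``lam = (1 + alpha) * lambda_lower``; the
    ``line_search`` mode minimizes ``G(lam)`` over a bounded bracket
    ``[lambda_lower * (1 + margin), lambda_lower * upper_factor]``.
    """

    alpha: float = 0.5
    lambda_mode: Literal["alpha_shortcut", "line_search"] = "alpha_shortcut"
    search_tolerance: float = 1e-8
    upper_factor: float = 100.0
    lower_margin: float = 1e-6

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.lambda_mode not in ("alpha_shortcut", "line_search"):
            raise ValueError("lambda_mode must be alpha_shortcut or line_search")


@dataclass
class RobustSolution:
    x: np.ndarray
    lam: float
    lambda_lower: float
    Q_hat: np.ndarray | sp.spmatrix
    W_hat: np.ndarray
    normal_matrix: np.ndarray | None = None
    cho_factor: tuple | None = None


def _weight_vector_or_dense(W, m: int):
    """Normalize W to either a positive diagonal vector or a dense matrix."""
    W = np.asarray(W, dtype=float) if not sp.issparse(W) else W.toarray()
    if W.ndim == 0:
        W = np.full(m, float(W))
    if W.ndim == 1:
        if W.shape != (m,):
            raise ValueError("diagonal W has wrong length")
        if np.any(W <= 0):
            raise ValueError("W must be positive definite")
        return W, True
    if W.shape != (m, m):
        raise ValueError("W has wrong shape")
    # symmetric PD check via Cholesky
    sla.cholesky(W, lower=True)
    return W, False


def _scaled_structure(U: UncertaintyModel):
    """Return (Mf, Ef_scaled, Eg_scaled) with phi absorbed into Ef/Eg."""
    Ef = U.Ef if U.Ef is not None else None
    Eg = U.Eg if U.Eg is not None else None
    phi = U.phi
    if Ef is not None:
        Ef = Ef * phi
    if Eg is not None:
        Eg = np.asarray(Eg, dtype=float) * phi
    return U.Mf, Ef, Eg


def lambda_lower_bound(W, U: UncertaintyModel) -> float:
    """``||Mf^T W Mf||_2``, the lower admissible value of ``lam``."""
    if U.is_null:
        return 0.0
    m = U.Mf.shape[0]
    w, diagonal = _weight_vector_or_dense(W, m)
    eta = U.scaled_identity_eta()
    if eta is not None and diagonal:
        return float(eta**2 * w.max())
    Mf = U.Mf.toarray() if sp.issparse(U.Mf) else np.asarray(U.Mf, dtype=float)
    WM = w[:, None] * Mf if diagonal else w @ Mf
    B = Mf.T @ WM
    return float(np.linalg.norm(B, 2))


def corrected_weight(W, U: UncertaintyModel, lam: float):
    """The corrected weighting ``W_hat``; diagonal stays diagonal.

    Returns either a length-m vector (diagonal case with ``Mf = eta I``) or a
    dense matrix.  A pseudo-inverse handles the singular bracket at
    ``lam == lambda_lower``.
    """
    m = U.Mf.shape[0]
    w, diagonal = _weight_vector_or_dense(W, m)
    eta = U.scaled_identity_eta()
    if eta is not None and diagonal:
        denom = lam - eta**2 * w
        out = w.copy()
        ok = denom > 1e-12 * max(lam, 1.0)
        out[ok] += (eta**2 * w[ok] ** 2) / denom[ok]
        return out
    Mf = U.Mf.toarray() if sp.issparse(U.Mf) else np.asarray(U.Mf, dtype=float)
    Wd = np.diag(w) if diagonal else w
    bracket = lam * np.eye(Mf.shape[1]) - Mf.T @ Wd @ Mf
    inv = np.linalg.pinv(bracket, hermitian=True)
    return Wd + Wd @ Mf @ inv @ Mf.T @ Wd


def _dense(M) -> np.ndarray:
    return M.toarray() if sp.issparse(M) else np.asarray(M, dtype=float)


def _solve_normal(N, rhs: np.ndarray, n: int):
    """Solve the (SPD) normal system, dense if small, Krylov otherwise."""
    if n <= DENSE_LIMIT:
        Nd = _dense(N)
        Nd = 0.5 * (Nd + Nd.T)
        try:
            c = sla.cho_factor(Nd)
            return sla.cho_solve(c, rhs), Nd, c
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise np.linalg.LinAlgError(f"normal matrix not positive definite: {exc}")
    Nsp = sp.csc_matrix(N)
    try:
        ilu = spilu(Nsp, drop_tol=1e-5, fill_factor=10)
        M = LinearOperator(Nsp.shape, ilu.solve)
    except RuntimeError:  # pragma: no cover - singular preconditioner
        M = None
    x, info = gmres(Nsp, rhs, M=M, rtol=1e-10, maxiter=2000)
    if info != 0:  # pragma: no cover
        raise RuntimeError(f"iterative solve of the normal equations failed (info={info})")
    return x, None, None


def _assemble_and_solve(A, b, W_hat, Q, lam, Ef, Eg, n):
    """Build Q_hat, the normal matrix and right-hand side; solve for x."""
    diagonal_w = isinstance(W_hat, np.ndarray) and W_hat.ndim == 1
    if diagonal_w:
        WA = (
            sp.diags(W_hat) @ A
            if sp.issparse(A)
            else W_hat[:, None] * np.asarray(A, dtype=float)
        )
    else:
        WA = W_hat @ _dense(A)
    AtWA = (A.T @ WA) if sp.issparse(A) else np.asarray(A).T @ WA
    rhs = (A.T @ (W_hat * b)) if diagonal_w else _dense(A).T @ (W_hat @ b)
    Q_hat = Q
    if lam > 0 and Ef is not None:
        EtE = Ef.T @ Ef
        Q_hat = Q + lam * EtE
        if Eg is not None and np.any(Eg):
            rhs = rhs + lam * np.asarray((Ef.T @ Eg)).ravel()
    N = Q_hat + AtWA
    x, Nd, c = _solve_normal(N, np.asarray(rhs).ravel(), n)
    return x, Q_hat, N, Nd, c


def robust_ls_solve(
    A,
    b: np.ndarray,
    W,
    Q,
    U: UncertaintyModel,
    params: RobustSolveParams | None = None,
    lam: float | None = None,
) -> RobustSolution:
    """Closed-form solution of the regularized min-max problem.

    Parameters
    ----------
    A : (m, n) matrix (sparse or dense)
        Nominal data matrix (the system matrix, or a residual-form copy).
    b : (m,) vector
        Nominal data.
    W : scalar, (m,) diagonal, or (m, m) dense
        Measurement weighting; must be positive definite.
    Q : (n, n) matrix
        Regularization / prior information matrix (positive semidefinite).
    U : UncertaintyModel
        Norm-bounded structure; ``U.is_null`` gives ordinary penalized WLS.
    lam : float, optional
        Use this regularization scalar instead of selecting one; must be at
        least the lower bound.
    """
    params = params or RobustSolveParams()
    b = np.asarray(b, dtype=float).ravel()
    m, n = (A.shape if sp.issparse(A) else np.asarray(A).shape)
    if b.size != m:
        raise ValueError("b has wrong length")
    if U.is_null:
        w, diagonal = _weight_vector_or_dense(W, m)
        W_hat = w if diagonal else w
        x, Q_hat, N, Nd, c = _assemble_and_solve(A, b, W_hat, Q, 0.0, None, None, n)
        return RobustSolution(x, 0.0, 0.0, Q_hat, W_hat, Nd, c)
    lam_lower = lambda_lower_bound(W, U)
    if lam is None:
        lam = select_lambda(A, b, W, Q, U, params)
    if lam < lam_lower * (1 - 1e-12):
        raise ValueError(f"lam={lam} is below the lower bound {lam_lower}")
    Mf, Ef, Eg = _scaled_structure(U)
    W_hat = corrected_weight(W, U, lam)
    x, Q_hat, N, Nd, c = _assemble_and_solve(A, b, W_hat, Q, lam, Ef, Eg, n)
    return RobustSolution(x, float(lam), lam_lower, Q_hat, W_hat, Nd, c)


def _g_cost(A, b, W, Q, U: UncertaintyModel, lam: float) -> float:
    """Scalar cost G(lam): the robust objective at the lam-parameterized x."""
    sol = robust_ls_solve(A, b, W, Q, U, lam=lam)
    x = sol.x
    Mf, Ef, Eg = _scaled_structure(U)
    r = (A @ x) - b
    w_hat = sol.W_hat
    if isinstance(w_hat, np.ndarray) and w_hat.ndim == 1:
        data_term = float(r @ (w_hat * r))
    else:
        data_term = float(r @ (w_hat @ r))
    Qd = Q
    reg_term = float(x @ ((Qd @ x) if (sp.issparse(Qd) or isinstance(Qd, np.ndarray)) else Qd @ x))
    s = (Ef @ x) - (Eg if Eg is not None else 0.0)
    struct_term = lam * float(np.dot(s, s))
    return reg_term + struct_term + data_term


def select_lambda(
    A,
    b: np.ndarray,
    W,
    Q,
    U: UncertaintyModel,
    params: RobustSolveParams | None = None,
) -> float:
    """Choose the regularization scalar per the configured mode."""
    params = params or RobustSolveParams()
    if U.is_null:
        return 0.0
    lam_lower = lambda_lower_bound(W, U)
    if params.lambda_mode == "alpha_shortcut":
        return (1.0 + params.alpha) * lam_lower
    lo = lam_lower * (1.0 + params.lower_margin)
    hi = lam_lower * params.upper_factor
    if lam_lower == 0.0:
        return 0.0
    res = minimize_scalar(
        lambda lam: _g_cost(A, b, W, Q, U, lam),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": params.search_tolerance * max(lam_lower, 1.0)},
    )
    return float(res.x)
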