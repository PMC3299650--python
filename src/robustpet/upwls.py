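"""Uncertainty-penalized WLS reconstruction as a robust state-space recursion.

Static PET is written as a state-space pair with identity transition: the
activity ``x(k+1) = x(k) + v(k)`` is constant up to small process noise, and
the (single, static) corrected sinogram is re-presented as the measurement at
every step ``k``.  Each step performs

* **update** — a-priori propagation ``x^- = x``, ``P^- = P + Qv`` (the model
  uncertainty enters the *measurement* matrix, so the time update is the
  standard covariance inflation);
* **correct** — a robust measurement update: the regularized min-max problem
  of :func:`robustpet.robust.robust_ls_solve` with the prior ``(x^-, P^-)``
  as quadratic regularizer and the uncertain pair ``(D, y)`` as data.  In
  residual form the structure vector becomes ``Eg - Ef x^-``, and the
  posterior covariance is the inverse corrected information matrix
  ``(Q_hat + D^T W_hat D)^{-1}``.

With a null uncertainty model every iterate coincides with the standard
penalized (information-form) Kalman recursion.  Iteration stops when two
consecutive normalized errors differ by at most ``epsilon`` (truth is known
in simulation studies; without truth the relative step size is used).
Negative pixels are clipped only in the final image.

``upwls_reconstruct_batch`` is an equivalent fast path for Monte-Carlo
studies: with scalar weighting, ``Mf = eta I`` and ``Qv = 0`` the covariance
recursion is identical for every data realization, so the per-iteration
dense factorization is shared and only the per-realization right-hand sides
differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .evaluation import has_converged, normalized_error
from .geometry import ActivityImage, ScanGeometry, Sinogram
from .penalty import PenaltyModel
from .projector import SystemMatrix, fbp_reconstruct
from .robust import RobustSolveParams, corrected_weight, lambda_lower_bound, robust_ls_solve
from .uncertainty import UncertaintyModel

__all__ = [
    "StateSpaceModel",
    "FilterState",
    "ConvergenceConfig",
    "upwls_init",
    "upwls_update",
    "upwls_correct",
    "upwls_reconstruct",
    "upwls_reconstruct_batch",
    "UPWLSResult",
]

logger = logging.getLogger(__name__)


@dataclass
class StateSpaceModel:
    """Static-mode state-space description of the scan.

    ``transition`` is the state matrix (``None`` means identity — static
    activity); ``qv`` scales the process-noise covariance ``Qv = qv * I``
    (default 0: the tracer distribution is exactly constant); ``R`` is the
    measurement-noise covariance as a scalar or per-bin diagonal vector,
    typically the plug-in Poisson variance ``max(prompt counts, 1)``.
    """

    R: np.ndarray | float
    qv: float = 0.0
    transition: np.ndarray | None = None
    R0: np.ndarray | float | None = None

    def __post_init__(self) -> None:
        if self.qv < 0:
            raise ValueError("qv must be nonnegative")
        r = np.asarray(self.R, dtype=float)
        if np.any(r <= 0):
            raise ValueError("R must be positive definite")

    def weight(self, m: int) -> np.ndarray:
        """Diagonal measurement weighting ``W = R^{-1}`` as a vector."""
        r = np.asarray(self.R, dtype=float)
        if r.ndim == 0:
            r = np.full(m, float(r))
        if r.shape != (m,):
            raise ValueError("R must be scalar or a length-m vector")
        return 1.0 / r


@dataclass
class FilterState:
    """Current estimate, covariance and carried information-form terms."""

    x_hat: np.ndarray
    P: np.ndarray
    k: int = 0
    aux: dict = field(default_factory=dict)

    @property
    def info(self) -> np.ndarray:
        """Information matrix ``P^{-1}`` (cached)."""
        cached = self.aux.get("info")
        if cached is not None:
            return cached
        n = self.P.shape[0]
        c = sla.cho_factor(0.5 * (self.P + self.P.T))
        info = sla.cho_solve(c, np.eye(n))
        self.aux["info"] = 0.5 * (info + info.T)
        return self.aux["info"]


@dataclass(frozen=True)
class ConvergenceConfig:
    epsilon: float = 1e-4
    max_iter: int = 200


@dataclass
class UPWLSResult:
    image: ActivityImage
    error_trace: list[float] = field(default_factory=list)
    step_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True
    state: FilterState | None = None


def _floor_spd(P: np.ndarray) -> np.ndarray:
    """Symmetrize and floor eigenvalues if positive definiteness is lost."""
    P = 0.5 * (P + P.T)
    try:
        sla.cholesky(P, lower=True)
        return P
    except np.linalg.LinAlgError:
        logger.warning("covariance lost positive definiteness; flooring eigenvalues")
        vals, vecs = np.linalg.eigh(P)
        floor = max(vals.max(), 1.0) * 1e-12
        return (vecs * np.maximum(vals, floor)) @ vecs.T


def upwls_init(
    y0: Sinogram,
    D: SystemMatrix,
    penalty: PenaltyModel,
    ssm: StateSpaceModel,
    x0_mode: str = "zero",
) -> FilterState:
    """Initial filter state: ``x(0)`` per mode and ``P(0) = Q^{-1}``.

    The smoothness penalty is ridge-augmented (see :class:`PenaltyModel`)
    because the pure Laplacian is singular; ``x0_mode`` is ``"zero"`` or
    ``"fbp"`` (filtered backprojection of ``y0`` for faster convergence).
    """
    n = D.geometry.n_voxels
    Q = penalty.beta * penalty.ridged().toarray()
    try:
        c = sla.cho_factor(Q)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "penalty matrix is singular; increase ridge_scale so Q + rho*I is invertible"
        ) from exc
    P0 = sla.cho_solve(c, np.eye(n))
    P0 = 0.5 * (P0 + P0.T)
    if x0_mode == "zero":
        x0 = np.zeros(n)
    elif x0_mode == "fbp":
        x0 = fbp_reconstruct(y0, D.geometry, system_matrix=D).values
    else:
        raise ValueError("x0_mode must be 'zero' or 'fbp'")
    return FilterState(x_hat=x0, P=P0, k=0, aux={"info": Q.copy()})


def upwls_update(
    state: FilterState,
    ssm: StateSpaceModel,
    U: UncertaintyModel | None = None,
    params: RobustSolveParams | None = None,
) -> FilterState:
    """A-priori propagation: ``x^- = A x``, ``P^- = A P A^T + Qv``.

    The transition is identity in static mode; the norm-bounded uncertainty
    concerns the measurement matrix, so it does not perturb the prediction
    (the robust prediction thus dominates the nominal one trivially in the
    Loewner order).
    """
    A = ssm.transition
    if A is None:
        x_pred = state.x_hat.copy()
        P_pred = state.P.copy()
    else:
        x_pred = A @ state.x_hat
        P_pred = A @ state.P @ A.T
    if ssm.qv > 0:
        P_pred = P_pred + ssm.qv * np.eye(P_pred.shape[0])
    P_pred = _floor_spd(P_pred)
    aux = {}
    if A is None and ssm.qv == 0 and "info" in state.aux:
        aux["info"] = state.aux["info"]  # information form carries over unchanged
    return FilterState(x_hat=x_pred, P=P_pred, k=state.k, aux=aux)


def upwls_correct(
    state: FilterState,
    y_k: Sinogram,
    D: SystemMatrix,
    U: UncertaintyModel,
    ssm: StateSpaceModel,
    params: RobustSolveParams | None = None,
) -> FilterState:
    """Robust measurement update of an a-priori state.

    Solves the min-max problem in residual form (unknown ``dx = x - x^-``)
    with data ``b = y - D x^-`` and shifted structure vector
    ``Eg - Ef x^-``; the posterior mean is ``x^- + dx`` and the posterior
    covariance the inverse of the corrected information matrix.
    """
    params = params or RobustSolveParams()
    m = D.geometry.n_rays
    W = ssm.weight(m)
    Q_prior = state.info
    b = y_k.values - D.entries @ state.x_hat
    if U.is_null:
        U_step = U
    else:
        Ef = U.Ef
        Eg = U.Eg if U.Eg is not None else np.zeros(Ef.shape[0])
        U_step = UncertaintyModel(
            Mf=U.Mf, Ef=Ef, Eg=np.asarray(Eg) - np.asarray(Ef @ state.x_hat).ravel(),
            phi=U.phi,
        )
    sol = robust_ls_solve(D.entries, b, W, Q_prior, U_step, params)
    x_new = state.x_hat + sol.x
    if sol.cho_factor is not None:
        P_new = sla.cho_solve(sol.cho_factor, np.eye(len(x_new)))
        info = sol.normal_matrix
    else:  # pragma: no cover - very large systems
        P_new = np.linalg.inv(sol.normal_matrix)
        info = sol.normal_matrix
    P_new = 0.5 * (P_new + P_new.T)
    aux = {"lam": sol.lam, "lambda_lower": sol.lambda_lower}
    if info is not None:
        aux["info"] = 0.5 * (info + info.T)
    return FilterState(x_hat=x_new, P=P_new, k=state.k + 1, aux=aux)


def upwls_reconstruct(
    y: Sinogram,
    D: SystemMatrix,
    penalty: PenaltyModel,
    ssm: StateSpaceModel,
    U: UncertaintyModel,
    params: RobustSolveParams | None = None,
    stop: ConvergenceConfig | None = None,
    x0_mode: str = "zero",
    x_true: ActivityImage | None = None,
) -> UPWLSResult:
    """Full UPWLS iteration on one (static) sinogram."""
    params = params or RobustSolveParams()
    stop = stop or ConvergenceConfig()
    state = upwls_init(y, D, penalty, ssm, x0_mode=x0_mode)
    result = UPWLSResult(image=ActivityImage(D.geometry, np.maximum(state.x_hat, 0)))
    prev_err = None
    converged = False
    scale = float(y.meta.get("scale", 1.0))
    for k in range(stop.max_iter):
        state = upwls_update(state, ssm, U, params)
        new_state = upwls_correct(state, y, D, U, ssm, params)
        step = float(
            np.linalg.norm(new_state.x_hat - state.x_hat)
            / max(np.linalg.norm(new_state.x_hat), 1e-30)
        )
        state = new_state
        result.step_trace.append(step)
        result.n_iter = k + 1
        if x_true is not None:
            est = ActivityImage(D.geometry, np.maximum(state.x_hat, 0) / scale)
            err = normalized_error(est, x_true)
            result.error_trace.append(err)
            crit_prev, crit_now = prev_err, err
        else:
            crit_prev = result.step_trace[-2] if k > 0 else None
            crit_now = step
        if crit_prev is not None and has_converged(crit_now, crit_prev, stop.epsilon):
            converged = True
            break
        prev_err = result.error_trace[-1] if x_true is not None else None
        if np.isinf(stop.epsilon):
            converged = True
            break
    if not converged and result.n_iter >= stop.max_iter:
        logger.warning("UPWLS reached max_iter=%d without meeting the stop rule", stop.max_iter)
    result.converged = converged
    result.image = ActivityImage(D.geometry, np.maximum(state.x_hat, 0))
    result.state = state
    return result


def upwls_reconstruct_batch(
    Y: np.ndarray,
    D: SystemMatrix,
    penalty: PenaltyModel,
    w_scalar: float,
    eta: float,
    params: RobustSolveParams | None = None,
    stop: ConvergenceConfig | None = None,
    x0: np.ndarray | None = None,
    x_true: ActivityImage | None = None,
    scale: float = 1.0,
) -> tuple[np.ndarray, list[list[float]], int]:
    """UPWLS for many realizations sharing one covariance recursion.

    Requires the conditions under which the covariance path is
    data-independent: scalar weighting ``w_scalar`` (plug-in Poisson weight
    from the protocol's expected mean counts), ``Mf = eta * I`` and
    ``qv = 0``.  ``Y`` is ``(R, m)``; returns the clipped ``(R, n)`` images,
    per-realization error traces (against ``x_true`` on the activity scale
    ``scale``) and the number of iterations run.
    """
    params = params or RobustSolveParams()
    stop = stop or ConvergenceConfig()
    Dm = D.entries
    m, n = Dm.shape
    if Y.ndim != 2 or Y.shape[1] != m:
        raise ValueError("Y must be (n_realizations, m)")
    R = Y.shape[0]
    w = np.full(m, w_scalar)
    U = UncertaintyModel(Mf=sp.identity(m, format="csr") * eta,
                         Ef=sp.identity(n, format="csr"), Eg=np.zeros(n), phi=1.0) \
        if eta > 0 else UncertaintyModel(None, None, None, phi=0.0)
    lam_lower = lambda_lower_bound(w, U)
    lam = (1.0 + params.alpha) * lam_lower if not U.is_null else 0.0
    w_hat_scalar = float(corrected_weight(w, U, lam)[0]) if not U.is_null else w_scalar
    J = penalty.beta * penalty.ridged().toarray()  # shared info matrix, P(0) = Q^{-1}
    G = (Dm.T @ Dm).toarray() * w_hat_scalar  # D^T W_hat D, constant over steps
    X = np.zeros((n, R)) if x0 is None else np.asarray(x0, dtype=float).T.copy()
    errors: list[list[float]] = [[] for _ in range(R)]
    prev = np.full(R, np.nan)
    n_iter = 0
    for k in range(stop.max_iter):
        K = J + G
        if lam > 0:
            K = K + lam * np.eye(n)
        K = 0.5 * (K + K.T)
        c = sla.cho_factor(K)
        resid = Y.T - (Dm @ X)  # (m, R)
        rhs = Dm.T @ (w_hat_scalar * resid)
        if lam > 0:
            rhs = rhs - lam * X  # structure shift Eg - Ef x^- with Eg = 0
        X = X + sla.cho_solve(c, rhs)
        J = K
        n_iter = k + 1
        if x_true is not None:
            est = np.maximum(X, 0) / scale
            truth = x_true.values
            errs = np.linalg.norm(est - truth[:, None], axis=0) / np.linalg.norm(truth)
            for r in range(R):
                errors[r].append(float(errs[r]))
            if k > 0 and np.all(np.abs(errs - prev) <= stop.epsilon):
                break
            prev = errs
    return np.maximum(X.T, 0), errors, n_iter
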