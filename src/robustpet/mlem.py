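"""Maximum-likelihood expectation-maximization (MLEM) reconstruction.

The classic multiplicative update for Poisson emission data,

    x  <-  x * D^T(y / (D x)) / D^T 1,

which preserves nonnegativity and never decreases the Poisson log-likelihood.
Corrected sinograms can contain negative bins after randoms/scatter
subtraction; MLEM requires nonnegative data, so negatives are clipped to zero
on input (the least-squares reconstructors receive the unclipped data).
Voxels with zero sensitivity (``D^T 1 = 0``, e.g. grid corners no ray
touches) are frozen at their initial value and a warning is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluation import normalized_error
from .geometry import ActivityImage, Sinogram
from .projector import SystemMatrix

__all__ = ["MLEMResult", "mlem_reconstruct"]

logger = logging.getLogger(__name__)

_TINY = 1e-30


@dataclass
class MLEMResult:
    image: ActivityImage
    log_likelihood: list[float] = field(default_factory=list)
    error_trace: list[float] = field(default_factory=list)
    n_iter: int = 0


def _poisson_loglik(y: np.ndarray, mean: np.ndarray) -> float:
    mean = np.maximum(mean, _TINY)
    return float(np.sum(y * np.log(mean) - mean))


def mlem_reconstruct(
    y: Sinogram,
    D: SystemMatrix,
    n_iter: int = 100,
    x0: ActivityImage | None = None,
    x_true: ActivityImage | None = None,
    epsilon: float | None = None,
) -> MLEMResult:
    """Run MLEM for ``n_iter`` iterations (or until the error stalls).

    When ``x_true`` is given, the normalized error is traced per iteration
    and, if ``epsilon`` is set, iteration stops once two consecutive errors
    differ by at most ``epsilon``.
    """
    if y.geometry != D.geometry:
        raise ValueError("sinogram geometry does not match system matrix")
    data = np.maximum(y.values, 0.0)
    if x0 is None:
        x = np.ones(D.geometry.n_voxels)
    else:
        x = x0.values.copy()
        if np.any(x <= 0):
            raise ValueError("MLEM initial image must be strictly positive")
    sens = D.entries.T @ np.ones(D.geometry.n_rays)
    alive = sens > 0
    if not np.all(alive):
        logger.warning(
            "MLEM: %d voxels have zero sensitivity and stay at their initial value",
            int(np.count_nonzero(~alive)),
        )
    result = MLEMResult(image=ActivityImage(D.geometry, x))
    prev_err = None
    for k in range(n_iter):
        proj = D.entries @ x
        ratio = data / np.maximum(proj, _TINY)
        update = D.entries.T @ ratio
        x = np.where(alive, x * update / np.where(alive, sens, 1.0), x)
        result.log_likelihood.append(_poisson_loglik(data, D.entries @ x))
        result.n_iter = k + 1
        if x_true is not None:
            err = normalized_error(ActivityImage(D.geometry, x), x_true)
            result.error_trace.append(err)
            if epsilon is not None and prev_err is not None and abs(err - prev_err) <= epsilon:
                break
            prev_err = err
    result.image = ActivityImage(D.geometry, x)
    return result
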