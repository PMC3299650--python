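"""Controlled system-matrix perturbations and their norm-bounded description.

Two views of model error live here.  ``perturb_system_matrix`` *generates*
a concrete perturbed detection matrix at a requested mean relative error:
every entry of ray ``i`` is multiplied by a log-normal factor
``f_i = exp(sigma * z_i)``, mimicking mis-calibrated attenuation/normalization
factors, which act along rays; ``sigma`` is calibrated by bisection so the
measured error matches the request.  ``make_norm_bounded_model`` *describes*
uncertainty of a given magnitude in the structured form consumed by the
robust solver: the perturbation set ``{Mf @ Delta @ Ef : ||Delta|| <= phi}``
with ``Delta`` an arbitrary contraction and ``Mf``, ``Ef`` fixed matrices.

The mean relative error between an exact matrix ``D`` and a perturbed one is
the average of ``|delta_ij| / D_ij`` over the stored nonzero entries of
``D`` — a scale-invariant summary, reported as a fraction (0.06 == "6%").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .projector import SystemMatrix

__all__ = [
    "SystemMatrixPerturbation",
    "UncertaintyModel",
    "relative_error",
    "perturb_system_matrix",
    "apply_perturbation",
    "make_norm_bounded_model",
]


@dataclass
class SystemMatrixPerturbation:
    """A concrete additive perturbation ``delta`` of a system matrix."""

    delta_entries: sp.csr_matrix
    requested_error: float
    seed: int
    measured_error: float = 0.0


@dataclass
class UncertaintyModel:
    """Norm-bounded uncertainty structure ``{Mf @ Delta @ Ef, ||Delta|| <= phi}``.

    ``Mf`` (m x p) and ``Ef`` (q x n) fix how the contraction enters the
    system matrix; ``Eg`` (length q) fixes how it enters the data.  Setting
    ``Mf = 0`` (or ``phi = 0``) recovers the accurate-model case, in which
    the robust solver coincides with ordinary regularized weighted least
    squares.
    """

    Mf: sp.spmatrix | np.ndarray | None
    Ef: sp.spmatrix | np.ndarray | None
    Eg: np.ndarray | None
    phi: float = 1.0

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("phi must be nonnegative")

    @property
    def is_null(self) -> bool:
        """True when the model describes no uncertainty at all."""
        if self.phi == 0.0 or self.Mf is None:
            return True
        if sp.issparse(self.Mf):
            return self.Mf.nnz == 0 or np.all(self.Mf.data == 0)
        return not np.any(self.Mf)

    def scaled_identity_eta(self) -> float | None:
        """Return ``eta`` when ``Mf = eta * I`` (enables fast diagonal paths)."""
        Mf = self.Mf
        if Mf is None:
            return 0.0
        if sp.issparse(Mf):
            if Mf.shape[0] != Mf.shape[1]:
                return None
            diag = Mf.diagonal()
            off = Mf - sp.diags(diag)
            if off.nnz and np.any(off.data != 0):
                return None
            if np.allclose(diag, diag[0]):
                return float(diag[0])
            return None
        Mf = np.asarray(Mf)
        if Mf.ndim != 2 or Mf.shape[0] != Mf.shape[1]:
            return None
        eta = float(Mf[0, 0])
        if np.array_equal(Mf, eta * np.eye(Mf.shape[0])):
            return eta
        return None


def relative_error(D_true: SystemMatrix, D_noisy: SystemMatrix) -> float:
    """Mean of ``|delta_ij| / D_ij`` over the nonzero entries of ``D_true``."""
    A = D_true.entries.tocsr()
    B = D_noisy.entries.tocsr()
    if A.shape != B.shape:
        raise ValueError("system matrices have different shapes")
    if A.nnz == 0:
        raise ValueError("reference system matrix is identically zero")
    coo = A.tocoo()
    noisy = np.asarray(B[coo.row, coo.col]).ravel()
    return float(np.mean(np.abs(noisy - coo.data) / coo.data))


def _row_factor_error(nnz_per_row: np.ndarray, z: np.ndarray, sigma: float) -> float:
    """Measured mean relative error for row factors exp(sigma * z)."""
    per_row = np.abs(np.exp(sigma * z) - 1.0)
    total = nnz_per_row.sum()
    return float((nnz_per_row * per_row).sum() / total)


def perturb_system_matrix(
    D: SystemMatrix,
    requested_error: float,
    seed: int = 0,
) -> SystemMatrixPerturbation:
    """Multiplicative per-ray perturbation hitting a requested mean error.

    The returned ``delta`` preserves the sparsity pattern of ``D`` and keeps
    ``D + delta`` nonnegative (the row factors are strictly positive).
    Deterministic given ``seed``.
    """
    if requested_error < 0:
        raise ValueError("requested_error must be nonnegative")
    A = D.entries.tocsr()
    m = A.shape[0]
    if requested_error == 0.0 or A.nnz == 0:
        delta = sp.csr_matrix(A.shape)
        return SystemMatrixPerturbation(delta, requested_error, seed, 0.0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2_000_001]))
    z = rng.standard_normal(m)
    nnz_per_row = np.diff(A.indptr)
    # bisection on sigma: the measured error is continuous and increasing
    lo, hi = 0.0, 0.5
    while _row_factor_error(nnz_per_row, z, hi) < requested_error:
        hi *= 2.0
        if hi > 64.0:  # pragma: no cover - unreachable for sane requests
            raise RuntimeError("failed to bracket the requested error level")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _row_factor_error(nnz_per_row, z, mid) < requested_error:
            lo = mid
        else:
            hi = mid
    sigma = 0.5 * (lo + hi)
    factors = np.exp(sigma * z)
    delta = (sp.diags(factors - 1.0) @ A).tocsr()
    measured = _row_factor_error(nnz_per_row, z, sigma)
    return SystemMatrixPerturbation(delta, requested_error, seed, measured)


def apply_perturbation(
    D: SystemMatrix, pert: SystemMatrixPerturbation
) -> SystemMatrix:
    """The perturbed system matrix ``D + delta``."""
    return SystemMatrix(D.geometry, (D.entries + pert.delta_entries).tocsr(),
                        provenance="perturbed")


def make_norm_bounded_model(D: SystemMatrix, error_level: float) -> UncertaintyModel:
    """Default norm-bounded envelope for system-matrix error of a given level.

    ``Mf = eta * I_m`` with ``eta = error_level * max row sum of D`` (the
    matrix infinity-norm), ``Ef = I_n``, ``Eg = 0`` and ``phi = 1``: a simple
    envelope whose members ``Mf @ Delta @ Ef`` have norm at most
    ``error_level * ||D||_inf`` — the magnitude of the perturbations produced
    by :func:`perturb_system_matrix` at the same level.  ``error_level = 0``
    yields the accurate-model case ``Mf = 0``.
    """
    if error_level < 0:
        raise ValueError("error_level must be nonnegative")
    m, n = D.entries.shape
    if error_level == 0.0:
        return UncertaintyModel(Mf=None, Ef=None, Eg=None, phi=0.0)
    row_sums = np.asarray(np.abs(D.entries).sum(axis=1)).ravel()
    eta = error_level * float(row_sums.max())
    Mf = sp.identity(m, format="csr") * eta
    Ef = sp.identity(n, format="csr")
    Eg = np.zeros(n)
    return UncertaintyModel(Mf=Mf, Ef=Ef, Eg=Eg, phi=1.0)
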