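"""Single-ray system matrix, forward/back projection and an FBP initializer.

The system matrix ``D`` maps voxel activity to expected bin counts.  Entry
``(i, j)`` is the Euclidean length of the intersection between ray ``i`` and
pixel ``j`` (the single-ray approximation: a longer traversal means a larger
detection sensitivity).  Rays are traced with a Siddon-style sweep over the
pixel grid lines, so row sums equal the chord length of the ray through the
field of view up to float round-off.

Conventions: pixel boundaries are half-open, and rays exactly tangent to a
pixel edge contribute zero (a measure-zero event for generic geometries).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.sparse as sp

from .geometry import ActivityImage, ScanGeometry, Sinogram

__all__ = [
    "SystemMatrix",
    "intersection_length",
    "build_system_matrix",
    "get_system_matrix",
    "forward_project",
    "back_project",
    "fbp_reconstruct",
]

_EPS = 1e-12


@dataclass
class SystemMatrix:
    """Sparse ``m x n`` nonnegative detection-sensitivity matrix."""

    geometry: ScanGeometry
    entries: sp.csr_matrix
    provenance: Literal["exact", "perturbed"] = "exact"

    def __post_init__(self) -> None:
        self.entries = sp.csr_matrix(self.entries)
        expected = (self.geometry.n_rays, self.geometry.n_voxels)
        if self.entries.shape != expected:
            raise ValueError(f"system matrix shape {self.entries.shape}, expected {expected}")
        if self.entries.nnz and self.entries.data.min() < 0:
            raise ValueError("system matrix entries must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape


def intersection_length(
    pixel_bounds: tuple[float, float, float, float],
    point: np.ndarray,
    direction: np.ndarray,
) -> float:
    """Length of the intersection of a ray with an axis-aligned rectangle.

    Parameters
    ----------
    pixel_bounds:
        ``(xmin, ymin, xmax, ymax)``.
    point, direction:
        A point on the (bi-infinite) ray and its unit direction vector.

    Returns 0.0 for disjoint or tangent configurations.  Pixel intervals are
    half-open ``[lo, hi)``: an axis-parallel ray lying exactly on a boundary
    belongs to the pixel whose lower edge it touches (so shared boundaries
    are never double counted and grid row sums stay exact).
    """
    point = np.asarray(point, dtype=float)
    direction = np.asarray(direction, dtype=float)
    norm = float(np.hypot(direction[0], direction[1]))
    if abs(norm - 1.0) > 1e-8:
        raise ValueError("direction must be a unit vector")
    xmin, ymin, xmax, ymax = pixel_bounds
    tmin, tmax = -np.inf, np.inf
    for axis, (lo, hi) in enumerate(((xmin, xmax), (ymin, ymax))):
        d, p = direction[axis], point[axis]
        if abs(d) < _EPS:
            if p < lo or p >= hi:  # half-open: the lower edge is inside
                return 0.0
            continue
        t1, t2 = (lo - p) / d, (hi - p) / d
        if t1 > t2:
            t1, t2 = t2, t1
        tmin, tmax = max(tmin, t1), min(tmax, t2)
    return float(max(0.0, tmax - tmin))


def _trace_ray(geom: ScanGeometry, point: np.ndarray, direction: np.ndarray):
    """Pixel indices and intersection lengths for one ray (Siddon sweep)."""
    w2, h2 = geom.width / 2.0, geom.height / 2.0
    px = geom.pixel_size
    tmin, tmax = -np.inf, np.inf
    for axis, half in enumerate((w2, h2)):
        d, p = direction[axis], point[axis]
        if abs(d) < _EPS:
            if p < -half or p >= half:  # half-open, as in intersection_length
                return None
            continue
        t1, t2 = (-half - p) / d, (half - p) / d
        if t1 > t2:
            t1, t2 = t2, t1
        tmin, tmax = max(tmin, t1), min(tmax, t2)
    if tmax - tmin <= _EPS:
        return None
    crossings = [np.array([tmin, tmax])]
    for axis, (count, half) in enumerate(((geom.grid_nx, w2), (geom.grid_ny, h2))):
        d, p = direction[axis], point[axis]
        if abs(d) < _EPS:
            continue
        lines = -half + px * np.arange(count + 1)
        t = (lines - p) / d
        crossings.append(t[(t > tmin) & (t < tmax)])
    ts = np.unique(np.concatenate(crossings))
    lengths = np.diff(ts)
    mids = point[None, :] + direction[None, :] * ((ts[:-1] + ts[1:]) / 2.0)[:, None]
    ix = np.clip(((mids[:, 0] + w2) / px).astype(int), 0, geom.grid_nx - 1)
    iy = np.clip(((mids[:, 1] + h2) / px).astype(int), 0, geom.grid_ny - 1)
    keep = lengths > _EPS
    return iy[keep] * geom.grid_nx + ix[keep], lengths[keep]


def build_system_matrix(geom: ScanGeometry) -> SystemMatrix:
    """Trace one ray through each (angle, bin) centre and assemble ``D``."""
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for a in range(geom.n_angles):
        for b in range(geom.n_bins):
            point, direction = geom.ray(a, b)
            traced = _trace_ray(geom, point, direction)
            if traced is None:
                continue
            j, lengths = traced
            i = a * geom.n_bins + b
            rows.append(np.full(j.size, i, dtype=np.int64))
            cols.append(j)
            vals.append(lengths)
    if rows:
        coo = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(geom.n_rays, geom.n_voxels),
        )
    else:  # pragma: no cover - degenerate geometry with no ray touching the FOV
        coo = sp.coo_matrix((geom.n_rays, geom.n_voxels))
    return SystemMatrix(geom, coo.tocsr(), provenance="exact")


@functools.lru_cache(maxsize=8)
def get_system_matrix(geom: ScanGeometry) -> SystemMatrix:
    """Memoized :func:`build_system_matrix` (geometries are hashable)."""
    return build_system_matrix(geom)


def forward_project(D: SystemMatrix, x: ActivityImage) -> Sinogram:
    """``y = D x`` (noiseless expected projections)."""
    if x.geometry != D.geometry:
        raise ValueError("image geometry does not match system matrix")
    return Sinogram(D.geometry, D.entries @ x.values, kind="noiseless")


def back_project(D: SystemMatrix, y: Sinogram) -> np.ndarray:
    """``D^T y``; an image-shaped vector, not necessarily nonnegative."""
    if y.geometry != D.geometry:
        raise ValueError("sinogram geometry does not match system matrix")
    return D.entries.T @ y.values


def _ramp_hann_filter(proj: np.ndarray, bin_width: float) -> np.ndarray:
    """Apply a Hann-windowed ramp filter along the bin axis of (angles, bins)."""
    n_bins = proj.shape[1]
    size = int(2 ** np.ceil(np.log2(max(64, 2 * n_bins))))
    freqs = np.fft.fftfreq(size, d=bin_width)
    f_nyq = 1.0 / (2.0 * bin_width)
    filt = 2.0 * np.abs(freqs) * 0.5 * (1.0 + np.cos(np.pi * freqs / f_nyq))
    spectrum = np.fft.fft(proj, n=size, axis=1) * filt[None, :]
    return np.real(np.fft.ifft(spectrum, axis=1))[:, :n_bins]


def fbp_reconstruct(
    y: Sinogram,
    geom: ScanGeometry,
    system_matrix: SystemMatrix | None = None,
) -> ActivityImage:
    """Filtered backprojection, used as a fast nonnegative initializer.

    The ramp-filtered sinogram is backprojected with the system-matrix
    transpose (keeping the package's single geometry convention) and the
    result is clipped to zero and rescaled by a least-squares fit of its
    forward projection to the data.  Accuracy is deliberately loose: this is
    an initial estimate for the iterative reconstructors, not a final image.
    """
    if y.kind not in ("corrected", "noiseless"):
        raise ValueError("FBP expects corrected or noiseless data")
    if geom.n_angles < 2:
        raise ValueError("FBP requires at least 2 projection angles")
    D = system_matrix if system_matrix is not None else get_system_matrix(geom)
    filtered = _ramp_hann_filter(y.as_2d(), geom.bin_width)
    x = D.entries.T @ filtered.ravel()
    x *= np.pi / (2.0 * geom.n_angles) / geom.pixel_size
    x = np.maximum(x, 0.0)
    proj = D.entries @ x
    denom = float(proj @ proj)
    scale = max(float(y.values @ proj) / denom, 0.0) if denom > 0 else 0.0
    return ActivityImage(geom, x * scale)
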