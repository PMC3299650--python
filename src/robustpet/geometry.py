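"""Scan geometry and the basic image/sinogram containers.

A 2-D parallel-beam acquisition is described by a :class:`ScanGeometry`: a
rectangular voxel grid of ``grid_ny`` rows by ``grid_nx`` columns and a set of
``n_angles`` projection angles uniformly spanning ``[0, pi)``, each with
``n_bins`` detector bins.  Both index spaces are flattened lexicographically
and that ordering is fixed package-wide:

* image: row-major, voxel ``j = iy * grid_nx + ix`` with ``(ix, iy) = (0, 0)``
  at the minimum-x / minimum-y corner of the field of view;
* sinogram: angle-major, ray ``i = angle_index * n_bins + bin_index``.

Angle 0 corresponds to rays travelling parallel to the y-axis; the grid is
centred on the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = ["ScanGeometry", "ActivityImage", "Sinogram", "default_geometry"]

SinogramKind = Literal["prompt", "delayed", "corrected", "noiseless"]


@dataclass(frozen=True)
class ScanGeometry:
    """Image grid plus parallel-beam projection layout.

    Parameters
    ----------
    grid_nx, grid_ny:
        Number of voxel columns / rows; the image has ``n = grid_nx * grid_ny``
        voxels.
    n_angles:
        Projection angles, uniform over ``[0, pi)``.
    n_bins:
        Detector bins per angle; the sinogram has ``m = n_angles * n_bins``
        entries.
    pixel_size, bin_width:
        Physical sizes in arbitrary (consistent) length units.
    """

    grid_nx: int
    grid_ny: int
    n_angles: int
    n_bins: int
    pixel_size: float = 1.0
    bin_width: float = 1.0

    def __post_init__(self) -> None:
        if self.grid_nx <= 0 or self.grid_ny <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.n_angles <= 0 or self.n_bins <= 0:
            raise ValueError("n_angles and n_bins must be positive")
        if self.pixel_size <= 0 or self.bin_width <= 0:
            raise ValueError("pixel_size and bin_width must be positive")

    @property
    def n_voxels(self) -> int:
        return self.grid_nx * self.grid_ny

    @property
    def n_rays(self) -> int:
        return self.n_angles * self.n_bins

    @property
    def width(self) -> float:
        return self.grid_nx * self.pixel_size

    @property
    def height(self) -> float:
        return self.grid_ny * self.pixel_size

    def angles(self) -> np.ndarray:
        return np.arange(self.n_angles) * (np.pi / self.n_angles)

    def bin_offsets(self) -> np.ndarray:
        """Signed detector offsets of the bin centres from the rotation axis."""
        return (np.arange(self.n_bins) - (self.n_bins - 1) / 2.0) * self.bin_width

    def ray(self, angle_index: int, bin_index: int) -> tuple[np.ndarray, np.ndarray]:
        """A point on the ray and its unit direction, for one (angle, bin)."""
        theta = angle_index * np.pi / self.n_angles
        u = np.array([np.cos(theta), np.sin(theta)])  # detector axis
        v = np.array([-np.sin(theta), np.cos(theta)])  # ray direction
        s = (bin_index - (self.n_bins - 1) / 2.0) * self.bin_width
        return s * u, v

    def pixel_bounds(self, ix: int, iy: int) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of pixel column ``ix``, row ``iy``."""
        x0 = -self.width / 2.0 + ix * self.pixel_size
        y0 = -self.height / 2.0 + iy * self.pixel_size
        return (x0, y0, x0 + self.pixel_size, y0 + self.pixel_size)


def default_geometry() -> ScanGeometry:
    """The package's reference desk-scale geometry (64x64, 60 angles, 95 bins)."""
    return ScanGeometry(grid_nx=64, grid_ny=64, n_angles=60, n_bins=95)


@dataclass
class ActivityImage:
    """Nonnegative voxelized radioactivity distribution (the unknown ``x``)."""

    geometry: ScanGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.geometry.n_voxels:
            raise ValueError(
                f"activity vector has length {self.values.size}, expected "
                f"{self.geometry.n_voxels}"
            )
        if np.any(self.values < 0):
            raise ValueError("activity values must be nonnegative")

    @classmethod
    def from_2d(cls, geometry: ScanGeometry, array: np.ndarray) -> "ActivityImage":
        array = np.asarray(array, dtype=float)
        if array.shape != (geometry.grid_ny, geometry.grid_nx):
            raise ValueError("2-D array shape does not match geometry")
        return cls(geometry, array.ravel())

    def as_2d(self) -> np.ndarray:
        return self.values.reshape(self.geometry.grid_ny, self.geometry.grid_nx)


@dataclass
class Sinogram:
    """Flattened projection data (the measurement ``y``).

    ``prompt`` and ``delayed`` sinograms hold nonnegative integer counts;
    ``corrected`` data (after randoms/scatter subtraction) may contain
    negative bins.  ``meta`` carries simulation bookkeeping such as the
    activity-to-counts scale.
    """

    geometry: ScanGeometry
    values: np.ndarray
    kind: SinogramKind = "noiseless"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.geometry.n_rays:
            raise ValueError(
                f"sinogram has length {self.values.size}, expected "
                f"{self.geometry.n_rays}"
            )
        if self.kind in ("prompt", "delayed"):
            if np.any(self.values < 0):
                raise ValueError(f"{self.kind} counts must be nonnegative")
            if not np.allclose(self.values, np.round(self.values)):
                raise ValueError(f"{self.kind} counts must be integers")

    def as_2d(self) -> np.ndarray:
        """(n_angles, n_bins) view of the flattened data."""
        return self.values.reshape(self.geometry.n_angles, self.geometry.n_bins)
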