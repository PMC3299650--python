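"""Analytic Shepp-Logan emission phantom.

The phantom is the standard contrast-enhanced ("modified") Shepp-Logan head:
ten ellipses on the unit square, each adding a constant value inside its
boundary.  Rasterization evaluates the ellipse sum at pixel centres, with the
grid mapped onto ``[-1, 1]`` per axis, so the phantom is available at any
grid size and is exactly reproducible.  All summed values are nonnegative
(background 0, brain tissue 0.2, skull 1.0, small lesions 0.3), which makes
the raster directly usable as an activity map.
"""

from __future__ import annotations

import numpy as np

from .geometry import ActivityImage, ScanGeometry

__all__ = ["SHEPP_LOGAN_ELLIPSES", "shepp_logan_phantom"]

# (additive value, semi-axis a, semi-axis b, centre x0, centre y0, angle deg)
SHEPP_LOGAN_ELLIPSES: tuple[tuple[float, float, float, float, float, float], ...] = (
    (1.0, 0.69, 0.92, 0.0, 0.0, 0.0),
    (-0.8, 0.6624, 0.8740, 0.0, -0.0184, 0.0),
    (-0.2, 0.1100, 0.3100, 0.22, 0.0, -18.0),
    (-0.2, 0.1600, 0.4100, -0.22, 0.0, 18.0),
    (0.1, 0.2100, 0.2500, 0.0, 0.35, 0.0),
    (0.1, 0.0460, 0.0460, 0.0, 0.1, 0.0),
    (0.1, 0.0460, 0.0460, 0.0, -0.1, 0.0),
    (0.1, 0.0460, 0.0230, -0.08, -0.605, 0.0),
    (0.1, 0.0230, 0.0230, 0.0, -0.606, 0.0),
    (0.1, 0.0230, 0.0460, 0.06, -0.605, 0.0),
)


def shepp_logan_phantom(geom: ScanGeometry) -> ActivityImage:
    """Rasterize the phantom at the pixel centres of ``geom``."""
    # pixel-centre coordinates mapped to [-1, 1] per axis
    xi = (np.arange(geom.grid_nx) + 0.5) / geom.grid_nx * 2.0 - 1.0
    eta = (np.arange(geom.grid_ny) + 0.5) / geom.grid_ny * 2.0 - 1.0
    gx, gy = np.meshgrid(xi, eta)
    values = np.zeros_like(gx)
    for level, a, b, x0, y0, phi_deg in SHEPP_LOGAN_ELLIPSES:
        phi = np.deg2rad(phi_deg)
        dx, dy = gx - x0, gy - y0
        xr = dx * np.cos(phi) + dy * np.sin(phi)
        yr = -dx * np.sin(phi) + dy * np.cos(phi)
        values += level * ((xr / a) ** 2 + (yr / b) ** 2 <= 1.0)
    return ActivityImage.from_2d(geom, np.maximum(values, 0.0))
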