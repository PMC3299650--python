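"""Seeded end-to-end fixture datasets for tests and demos.

``make_fixture`` builds a complete scan container at one of two preset
scales — *tiny* (8x8 grid, 10 angles, 11 bins, 1k counts) or *small*
(32x32, 30 angles, 47 bins, 20k counts) — with the phantom, the exact and
6%-perturbed system matrices and 3 simulated realizations.  Deterministic
per seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .acquisition import ScanProtocol, correct_sinogram, simulate_scan
from .geometry import ScanGeometry
from .io import ScanDataset, save_scan
from .phantom import shepp_logan_phantom
from .projector import build_system_matrix
from .uncertainty import perturb_system_matrix

__all__ = ["FIXTURE_PRESETS", "make_fixture", "build_dataset"]

FIXTURE_PRESETS = {
    "tiny": dict(grid=8, n_angles=10, n_bins=11, total_counts=1_000.0),
    "small": dict(grid=32, n_angles=30, n_bins=47, total_counts=20_000.0),
}


def build_dataset(
    geom: ScanGeometry,
    proto: ScanProtocol,
    matrix_error: float = 0.06,
) -> ScanDataset:
    """Simulate a full dataset (truth, D, perturbation, all realizations)."""
    phantom = shepp_logan_phantom(geom)
    D = build_system_matrix(geom)
    pert = perturb_system_matrix(D, matrix_error, seed=proto.seed)
    R, m = proto.n_realizations, geom.n_rays
    prompts = np.empty((R, m))
    delays = np.empty((R, m))
    corrected = np.empty((R, m))
    scale = 1.0
    for r in range(R):
        prompt, delayed = simulate_scan(phantom, D, proto, realization=r)
        corr = correct_sinogram(prompt, delayed, proto)
        prompts[r], delays[r], corrected[r] = prompt.values, delayed.values, corr.values
        scale = corr.meta["scale"]
    return ScanDataset(
        geometry=geom, protocol=proto, phantom=phantom, system_matrix=D,
        perturbation=pert, prompts=prompts, delays=delays, corrected=corrected,
        scale=scale,
    )


def make_fixture(size: str, seed: int = 0, out_dir=".") -> Path:
    """Write the preset dataset ``<out_dir>/scan_<size>.h5`` and return its path."""
    if size not in FIXTURE_PRESETS:
        raise ValueError(f"size must be one of {sorted(FIXTURE_PRESETS)}")
    preset = FIXTURE_PRESETS[size]
    geom = ScanGeometry(
        grid_nx=preset["grid"], grid_ny=preset["grid"],
        n_angles=preset["n_angles"], n_bins=preset["n_bins"],
    )
    proto = ScanProtocol(
        total_counts=preset["total_counts"], n_realizations=3, seed=seed
    )
    dataset = build_dataset(geom, proto, matrix_error=0.06)
    out = Path(out_dir) / f"scan_{size}.h5"
    out.parent.mkdir(parents=True, exist_ok=True)
    save_scan(out, dataset)
    return out
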