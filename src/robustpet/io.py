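"""On-disk formats: HDF5 scan containers, NIfTI images, CSV/plain-text.

A *scan container* is one HDF5 file holding everything a reconstruction run
needs: the ground-truth phantom, the exact system matrix (CSR triplet), an
optional perturbation with its request/seed metadata, and the per-realization
prompt / delayed / corrected sinograms.  Geometry and protocol parameters are
stored as root attributes so the container is self-describing.

Reconstructed images are written as 2-D NIfTI slices; small fixtures and
traces use plain text (CSV / whitespace matrices).
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .acquisition import ScanProtocol
from .geometry import ActivityImage, ScanGeometry, Sinogram
from .projector import SystemMatrix
from .uncertainty import SystemMatrixPerturbation

__all__ = [
    "ScanDataset",
    "save_scan",
    "load_scan",
    "save_image_nifti",
    "load_image_nifti",
    "save_image_text",
    "load_image_text",
    "sinogram_to_csv",
    "sinogram_from_csv",
]

_GEOM_ATTRS = ("grid_nx", "grid_ny", "n_angles", "n_bins", "pixel_size", "bin_width")
_PROTO_ATTRS = ("total_counts", "random_fraction", "scatter_fraction",
                "n_realizations", "seed")


@dataclass
class ScanDataset:
    """In-memory view of a scan container."""

    geometry: ScanGeometry
    protocol: ScanProtocol
    phantom: ActivityImage
    system_matrix: SystemMatrix
    perturbation: SystemMatrixPerturbation | None
    prompts: np.ndarray  # (R, m) integer counts
    delays: np.ndarray
    corrected: np.ndarray  # (R, m) float
    scale: float

    def prompt(self, r: int) -> Sinogram:
        meta = {"scale": self.scale, "realization": r}
        return Sinogram(self.geometry, self.prompts[r], kind="prompt", meta=meta)

    def corrected_sinogram(self, r: int) -> Sinogram:
        meta = {"scale": self.scale, "realization": r}
        return Sinogram(self.geometry, self.corrected[r], kind="corrected", meta=meta)


def _write_sparse(group: h5py.Group, M: sp.csr_matrix) -> None:
    M = sp.csr_matrix(M)
    group.create_dataset("data", data=M.data)
    group.create_dataset("indices", data=M.indices)
    group.create_dataset("indptr", data=M.indptr)
    group.attrs["shape"] = M.shape


def _read_sparse(group: h5py.Group) -> sp.csr_matrix:
    return sp.csr_matrix(
        (group["data"][()], group["indices"][()], group["indptr"][()]),
        shape=tuple(group.attrs["shape"]),
    )


def save_scan(path, dataset: ScanDataset) -> None:
    with h5py.File(path, "w") as f:
        for name in _GEOM_ATTRS:
            f.attrs[name] = getattr(dataset.geometry, name)
        for name in _PROTO_ATTRS:
            f.attrs[name] = getattr(dataset.protocol, name)
        f.attrs["scale"] = dataset.scale
        f.attrs["sinogram_ordering"] = "angle-major"
        f.attrs["image_ordering"] = "row-major"
        f.create_dataset("phantom", data=dataset.phantom.as_2d())
        _write_sparse(f.create_group("system_matrix"), dataset.system_matrix.entries)
        if dataset.perturbation is not None:
            g = f.create_group("perturbation")
            _write_sparse(g, dataset.perturbation.delta_entries)
            g.attrs["requested_error"] = dataset.perturbation.requested_error
            g.attrs["measured_error"] = dataset.perturbation.measured_error
            g.attrs["seed"] = dataset.perturbation.seed
        f.create_dataset("prompts", data=dataset.prompts.astype(np.int64))
        f.create_dataset("delays", data=dataset.delays.astype(np.int64))
        f.create_dataset("corrected", data=dataset.corrected)


def load_scan(path) -> ScanDataset:
    with h5py.File(path, "r") as f:
        geom = ScanGeometry(
            grid_nx=int(f.attrs["grid_nx"]), grid_ny=int(f.attrs["grid_ny"]),
            n_angles=int(f.attrs["n_angles"]), n_bins=int(f.attrs["n_bins"]),
            pixel_size=float(f.attrs["pixel_size"]), bin_width=float(f.attrs["bin_width"]),
        )
        proto = ScanProtocol(
            total_counts=float(f.attrs["total_counts"]),
            random_fraction=float(f.attrs["random_fraction"]),
            scatter_fraction=float(f.attrs["scatter_fraction"]),
            n_realizations=int(f.attrs["n_realizations"]),
            seed=int(f.attrs["seed"]),
        )
        phantom = ActivityImage.from_2d(geom, f["phantom"][()])
        D = SystemMatrix(geom, _read_sparse(f["system_matrix"]))
        pert = None
        if "perturbation" in f:
            g = f["perturbation"]
            pert = SystemMatrixPerturbation(
                delta_entries=_read_sparse(g),
                requested_error=float(g.attrs["requested_error"]),
                seed=int(g.attrs["seed"]),
                measured_error=float(g.attrs["measured_error"]),
            )
        return ScanDataset(
            geometry=geom, protocol=proto, phantom=phantom, system_matrix=D,
            perturbation=pert, prompts=f["prompts"][()].astype(float),
            delays=f["delays"][()].astype(float), corrected=f["corrected"][()],
            scale=float(f.attrs["scale"]),
        )


def save_image_nifti(path, image: ActivityImage) -> None:
    px = image.geometry.pixel_size
    affine = np.diag([px, px, 1.0, 1.0])
    nib.save(nib.Nifti1Image(image.as_2d().astype(np.float64), affine), str(path))


def load_image_nifti(path, geometry: ScanGeometry) -> ActivityImage:
    data = np.asanyarray(nib.load(str(path)).dataobj)
    return ActivityImage.from_2d(geometry, np.squeeze(data))


def save_image_text(path, image: ActivityImage) -> None:
    np.savetxt(path, image.as_2d())


def load_image_text(path, geometry: ScanGeometry) -> ActivityImage:
    return ActivityImage.from_2d(geometry, np.loadtxt(path))


def sinogram_to_csv(path, sino: Sinogram) -> None:
    geom = sino.geometry
    angles = np.repeat(np.arange(geom.n_angles), geom.n_bins)
    bins = np.tile(np.arange(geom.n_bins), geom.n_angles)
    pd.DataFrame(
        {"angle_index": angles, "bin_index": bins, "value": sino.values}
    ).to_csv(path, index=False)


def sinogram_from_csv(path, geometry: ScanGeometry, kind: str = "corrected") -> Sinogram:
    df = pd.read_csv(path)
    values = np.zeros(geometry.n_rays)
    idx = df["angle_index"].to_numpy() * geometry.n_bins + df["bin_index"].to_numpy()
    values[idx] = df["value"].to_numpy()
    return Sinogram(geometry, values, kind=kind)
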