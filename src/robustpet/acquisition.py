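"""Simulation of prompt/delayed-window PET coincidence measurements.

The scan model follows the usual 2-D emission protocol: the expected true
coincidences are the forward projection of the activity map, scaled so that
their total equals the requested count budget; randoms and scatter contribute
spatially uniform mean fields set as fractions of the true total; the prompt
window records ``Poisson(trues + randoms + scatter)`` and the delayed window
records an independent ``Poisson(randoms)`` realization.  Randoms correction
is the delayed-window subtraction; scatter is removed by subtracting its
known uniform mean, which isolates reconstruction behaviour from
scatter-estimation error.  Corrected data may therefore contain negative
bins; least-squares reconstructors consume them as-is while MLEM clips at
zero (documented in :mod:`robustpet.mlem`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ActivityImage, Sinogram
from .projector import SystemMatrix

__all__ = ["ScanProtocol", "simulate_scan", "correct_sinogram"]


@dataclass(frozen=True)
class ScanProtocol:
    """Count budget and contamination levels of one simulated scan.

    Defaults are the study conditions used throughout the package: a 100k
    true-coincidence budget with uniform randoms at 60% and uniform scatter
    at 20% of the trues, and 50 Monte-Carlo realizations.
    """

    total_counts: float = 100_000.0
    random_fraction: float = 0.60
    scatter_fraction: float = 0.20
    n_realizations: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_counts <= 0:
            raise ValueError("total_counts must be positive")
        for name in ("random_fraction", "scatter_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_realizations <= 0:
            raise ValueError("n_realizations must be positive")


def _mean_fields(x: ActivityImage, D: SystemMatrix, proto: ScanProtocol):
    """Expected trues, uniform randoms/scatter means, and the count scale."""
    y_clean = D.entries @ x.values
    total = float(y_clean.sum())
    if total <= 0.0:
        raise ValueError(
            "forward projection is identically zero; cannot scale to the count budget"
        )
    scale = proto.total_counts / total
    m = D.geometry.n_rays
    trues = scale * y_clean
    randoms = np.full(m, proto.random_fraction * proto.total_counts / m)
    scatter = np.full(m, proto.scatter_fraction * proto.total_counts / m)
    return trues, randoms, scatter, scale


def simulate_scan(
    x: ActivityImage,
    D: SystemMatrix,
    proto: ScanProtocol,
    realization: int = 0,
) -> tuple[Sinogram, Sinogram]:
    """One Poisson realization of (prompt, delayed) sinograms.

    Deterministic given ``(proto.seed, realization)``.  The prompt sinogram's
    ``meta`` records the activity-to-counts ``scale`` and the known
    contamination means used later by :func:`correct_sinogram`.
    """
    if x.geometry != D.geometry:
        raise ValueError("image geometry does not match system matrix")
    if realization < 0:
        raise ValueError("realization index must be nonnegative")
    trues, randoms, scatter, scale = _mean_fields(x, D, proto)
    rng = np.random.default_rng(np.random.SeedSequence([proto.seed, realization]))
    prompt_counts = rng.poisson(trues + randoms + scatter)
    delayed_counts = rng.poisson(randoms)
    meta = {
        "scale": scale,
        "random_mean": float(randoms[0]),
        "scatter_mean": float(scatter[0]),
        "realization": realization,
    }
    prompt = Sinogram(D.geometry, prompt_counts, kind="prompt", meta=dict(meta))
    delayed = Sinogram(D.geometry, delayed_counts, kind="delayed", meta=dict(meta))
    return prompt, delayed


def correct_sinogram(
    prompt: Sinogram,
    delayed: Sinogram,
    proto: ScanProtocol,
) -> Sinogram:
    """Randoms/scatter-corrected data: prompt - delayed - uniform scatter mean."""
    if prompt.kind != "prompt" or delayed.kind != "delayed":
        raise ValueError("expected a (prompt, delayed) sinogram pair")
    if prompt.geometry != delayed.geometry:
        raise ValueError("prompt and delayed geometries differ")
    m = prompt.geometry.n_rays
    scatter_mean = prompt.meta.get(
        "scatter_mean", proto.scatter_fraction * proto.total_counts / m
    )
    values = prompt.values - delayed.values - scatter_mean
    meta = dict(prompt.meta)
    return Sinogram(prompt.geometry, values, kind="corrected", meta=meta)
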