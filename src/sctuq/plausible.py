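"""'Plausible' synthetic-CT ensembles: error scenarios for dose propagation.

Each MC-dropout sample is perturbed once by independent per-voxel Laplacian
noise drawn at the predicted aleatoric scale, then converted back to HU and
clipped to the clinical range. The K = T perturbed volumes (one perturbation
per dropout sample, 50 total by default) carry both uncertainty sources:
their voxelwise variance approaches Var_MCD + 2 sigma_data^2 (the Laplace
variance is 2 b^2) away from the clip boundaries.

sigma_data is interpreted as the Laplace scale parameter b, consistent with
the training loss whose per-voxel optimum is the mean absolute residual; pass
``scale_is_std=True`` to reinterpret it as a standard deviation (b = sigma /
sqrt(2)).
"""

from __future__ import annotations

import dataclasses
from typing import List

import numpy as np

from .core import Volume, log_stage, spawn_seeds
from .uncertainty import McdEnsemble

HU_CLIP = (-1000.0, 3000.0)


@dataclasses.dataclass
class PlausibleSet:
    """K perturbed sCT volumes (HU) with the scale map and seed that made them."""

    members: List[Volume]
    scale_map: Volume  # Laplace scale used, normalized units
    seed: int

    @property
    def K(self) -> int:
        return len(self.members)


def sample_laplace_noise(scale_map: Volume, seed: int) -> Volume:
    """Independent Laplace(0, b(x)) draws; zero-scale voxels return exactly 0."""
    b = scale_map.values.astype(np.float64)
    if (b < 0).any():
        raise ValueError("scale map must be non-negative")
    rng = np.random.default_rng(seed)
    unit = rng.laplace(0.0, 1.0, size=scale_map.shape)
    return scale_map.like(unit * b, semantics="scale")


def generate_plausible_set(ensemble: McdEnsemble, sigma_data: Volume, K: int,
                           seed: int, allow_reuse: bool = False,
                           scale_is_std: bool = False) -> PlausibleSet:
    """Perturb MCD samples with Laplacian noise at the aleatoric scale.

    Member k is ``clip(1000 * (y_k + Laplace(0, b)), -1000, 3000)`` with an
    independent seeded draw per member; K may not exceed the ensemble size T
    unless ``allow_reuse=True`` (members then cycle through the T samples).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > ensemble.T and not allow_reuse:
        raise ValueError(f"K={K} exceeds ensemble size T={ensemble.T} "
                         "(pass allow_reuse=True to cycle samples)")
    ensemble.samples[0].check_geometry(sigma_data)
    b = sigma_data.values.astype(np.float64)
    if scale_is_std:
        b = b / np.sqrt(2.0)
    scale_map = sigma_data.like(b, semantics="scale")
    log_stage("plausible", seed, {"K": K, "scale_is_std": scale_is_std})
    member_seeds = spawn_seeds(seed, K)
    members = []
    for k in range(K):
        y = ensemble.samples[k % ensemble.T].values.astype(np.float64)
        noise = sample_laplace_noise(scale_map, member_seeds[k]).values.astype(np.float64)
        hu = np.clip(1000.0 * (y + noise), *HU_CLIP)
        members.append(ensemble.samples[0].like(hu, semantics="HU"))
    return PlausibleSet(members=members, scale_map=scale_map, seed=seed)
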