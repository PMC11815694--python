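"""Synthetic paired CT / CBCT phantoms with known ground-truth degradations.

Each phantom is a simple head-like anatomy — a soft-tissue body ellipsoid on an
air background with embedded bone, an air cavity, a spherical target volume and
two lateral organs at risk — plus the degradations that make cone-beam CT hard
to use directly: a smooth radial shading (cupping) field, a few streak lines, a
global HU offset, and per-voxel Laplacian noise whose scale ``b(x)`` is linked
to tissue class. The exact scale map is returned so that downstream estimators
can be validated against ground truth.

Soft tissue and bone carry white Gaussian HU heterogeneity (``texture_sigma``).
This voxel-scale anatomical content is present in both CT and CBCT but is not
inferable from a voxel's neighbourhood, which makes the injected CBCT noise
irreducible for a translation network — the property that real CBCT/CT pairs
owe to registration residuals and anatomical change, and the reason a
heteroscedastic loss can recover the noise scale at all.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import StructureSet, Volume, log_stage, spawn_seeds

HU_AIR = -1000.0
HU_SOFT = 40.0
HU_BONE = 700.0
HU_PTV = 60.0
HU_OAR = 30.0
HU_CLIP = (-1000.0, 3000.0)


class PhantomConfigError(ValueError):
    """Structure placement impossible (or invalid) at the requested grid size."""


@dataclasses.dataclass
class PhantomConfig:
    """Geometry, artifact and noise parameters of one paired phantom.

    Laplace scales are given in HU per region label; regions not listed fall
    back to ``body`` (inside the external contour) or ``background`` (outside).
    All amplitudes in HU. Structure sizes are fractions of the grid half-extent
    so that one config scales across grid sizes.
    """

    shape: Tuple[int, int, int] = (64, 64, 32)
    spacing: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    anatomy_seed: int = 0
    noise_seed: int = 0
    laplace_scales: Dict[str, float] = dataclasses.field(
        default_factory=lambda: {"body": 50.0, "bone": 10.0, "background": 10.0}
    )
    shading_amplitude: float = 40.0
    streak_count: int = 6
    streak_amplitude: float = 30.0
    hu_offset: float = 20.0
    texture_sigma: float = 100.0
    # structure geometry (fractions of half-extent per axis)
    body_axes: Tuple[float, float, float] = (0.78, 0.72, 0.9)
    bone_axes: Tuple[float, float, float] = (0.2, 0.16, 0.55)
    bone_center: Tuple[float, float, float] = (0.0, -0.32, 0.0)
    air_radius: float = 0.12
    air_center: Tuple[float, float, float] = (0.0, 0.3, 0.0)
    ptv_radius: float = 0.2
    ptv_center: Tuple[float, float, float] = (0.12, 0.1, 0.0)
    oar_radius: float = 0.13
    oar_offset: float = 0.45

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.shape):
            raise PhantomConfigError("each grid axis must have at least 8 voxels")
        if any(b < 0 for b in self.laplace_scales.values()):
            raise PhantomConfigError("Laplace scales must be non-negative")


@dataclasses.dataclass
class PairedSample:
    """A CT/CBCT pair with structures and the exact corruption ground truth."""

    ct: Volume
    cbct: Volume
    structures: StructureSet
    true_scale: Volume  # per-voxel Laplace scale b(x) in HU, semantics="scale"
    artifacts: Volume   # deterministic artifact field (shading+streaks+offset), HU
    ood: bool = False


def _ellipsoid(coords, center, semi_axes) -> np.ndarray:
    u = sum(((c - cc) / a) ** 2 for c, cc, a in zip(coords, center, semi_axes))
    return u <= 1.0


def _build_masks(cfg: PhantomConfig) -> Dict[str, np.ndarray]:
    shape = np.asarray(cfg.shape, dtype=float)
    half = (shape - 1) / 2.0
    coords = np.meshgrid(*[np.arange(n, dtype=float) for n in cfg.shape], indexing="ij")
    center = half

    def scaled(fracs):
        return [half[i] * fracs[i] for i in range(3)]

    def offset(fracs):
        return [center[i] + half[i] * fracs[i] for i in range(3)]

    body = _ellipsoid(coords, center, scaled(cfg.body_axes))
    bone = _ellipsoid(coords, offset(cfg.bone_center), scaled(cfg.bone_axes))
    air = _ellipsoid(coords, offset(cfg.air_center), [half.min() * cfg.air_radius] * 3)
    ptv = _ellipsoid(coords, offset(cfg.ptv_center), [half.min() * cfg.ptv_radius] * 3)
    oar_l = _ellipsoid(coords, offset((0.0, cfg.oar_offset, 0.0)), [half.min() * cfg.oar_radius] * 3)
    oar_r = _ellipsoid(coords, offset((0.0, -cfg.oar_offset, 0.0)), [half.min() * cfg.oar_radius] * 3)

    masks = {"external": body, "bone": bone, "air": air, "ptv": ptv,
             "oar_left": oar_l, "oar_right": oar_r}
    for label in ("bone", "air", "ptv", "oar_left", "oar_right"):
        if not masks[label].any():
            raise PhantomConfigError(f"structure {label!r} is empty at grid {cfg.shape}")
        if np.any(masks[label] & ~body):
            raise PhantomConfigError(f"structure {label!r} extends outside the body")
    # keep tissue classes disjoint where they collide
    masks["bone"] &= ~masks["air"]
    masks["ptv"] &= ~(masks["bone"] | masks["air"])
    return masks


def _scale_map(cfg: PhantomConfig, masks: Dict[str, np.ndarray]) -> np.ndarray:
    scales = cfg.laplace_scales
    b = np.full(cfg.shape, float(scales.get("background", 0.0)))
    body = masks["external"]
    b[body] = float(scales.get("body", 0.0))
    for label in ("bone", "air", "ptv", "oar_left", "oar_right"):
        if label in scales:
            b[masks[label]] = float(scales[label])
    return b


def _artifact_field(cfg: PhantomConfig, masks: Dict[str, np.ndarray],
                    rng: np.random.Generator) -> np.ndarray:
    nx, ny, nz = cfg.shape
    half = (np.asarray(cfg.shape, dtype=float) - 1) / 2.0
    x = np.arange(nx, dtype=float)[:, None] - half[0]
    y = np.arange(ny, dtype=float)[None, :] - half[1]
    ax = half[0] * cfg.body_axes[0]
    ay = half[1] * cfg.body_axes[1]

    # Cupping: low-order radial polynomial in the axial plane, zero-mean-ish
    # over the body (centre depressed, rim raised), constant along z.
    u2 = np.clip((x / ax) ** 2 + (y / ay) ** 2, 0.0, 1.44)
    shading2d = cfg.shading_amplitude * (u2 - 0.5)

    # Streaks: random-angle lines through the axial plane with a Gaussian
    # profile (sigma = 1 voxel), random sign and sub-maximal amplitude.
    streaks2d = np.zeros((nx, ny))
    for _ in range(int(cfg.streak_count)):
        theta = rng.uniform(0.0, np.pi)
        rho = rng.uniform(-0.6, 0.6) * min(ax, ay)
        sign = rng.choice([-1.0, 1.0])
        amp = sign * cfg.streak_amplitude * rng.uniform(0.5, 1.0)
        d = x * np.cos(theta) + y * np.sin(theta) - rho
        streaks2d = streaks2d + amp * np.exp(-0.5 * d ** 2)

    field2d = shading2d + streaks2d + cfg.hu_offset
    return np.repeat(field2d[:, :, None], nz, axis=2)


def generate_phantom_pair(config: PhantomConfig) -> PairedSample:
    """Generate one paired pseudo-CT / pseudo-CBCT sample.

    ``cbct = clip(ct + artifacts + Laplace(0, b(x)), -1000, 3000)`` — noise is
    injected before the final HU clip, so clipping censors extreme draws the
    way a clinical HU range would.
    """
    masks_np = _build_masks(config)
    rng_anat = np.random.default_rng(config.anatomy_seed)
    rng_noise = np.random.default_rng(config.noise_seed)

    ct = np.full(config.shape, HU_AIR)
    ct[masks_np["external"]] = HU_SOFT
    ct[masks_np["oar_left"] | masks_np["oar_right"]] = HU_OAR
    ct[masks_np["ptv"]] = HU_PTV
    ct[masks_np["bone"]] = HU_BONE
    ct[masks_np["air"]] = HU_AIR
    tissue = masks_np["external"] & ~masks_np["air"]
    if config.texture_sigma > 0:
        ct = ct + config.texture_sigma * rng_anat.standard_normal(config.shape) * tissue
    ct = np.clip(ct, *HU_CLIP)

    artifacts = _artifact_field(config, masks_np, rng_noise)
    b_map = _scale_map(config, masks_np)
    # unit Laplace draws scaled afterwards: b = 0 yields exactly 0 noise
    noise = rng_noise.laplace(0.0, 1.0, size=config.shape) * b_map
    cbct = np.clip(ct + artifacts + noise, *HU_CLIP)

    structures = StructureSet(
        {label: Volume(m.astype(np.float32), config.spacing, semantics="mask")
         for label, m in masks_np.items()}
    )
    log_stage("phantom", config.noise_seed, config)
    return PairedSample(
        ct=Volume(ct, config.spacing, semantics="HU"),
        cbct=Volume(cbct, config.spacing, semantics="HU"),
        structures=structures,
        true_scale=Volume(b_map, config.spacing, semantics="scale"),
        artifacts=Volume(artifacts, config.spacing, semantics="HU"),
    )


def generate_cohort(n: int, base_config: Optional[PhantomConfig] = None,
                    seed: int = 0, ood: bool = False,
                    ood_factor: float = 1.8) -> List[PairedSample]:
    """Generate ``n`` phantoms with per-sample jittered anatomy and artifacts.

    Ellipsoid axes, structure centres and artifact amplitudes are jittered by
    seeded draws so no two samples share an anatomy. With ``ood=True`` the
    artifact amplitudes and noise scales are multiplied by ``ood_factor``,
    emulating data from an unseen imaging centre.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    base = base_config or PhantomConfig()
    master = np.random.default_rng(seed)
    samples = []
    for k in range(n):
        anat_seed, noise_seed = spawn_seeds(int(master.integers(2 ** 31)), 2)
        jit = np.random.default_rng(anat_seed)
        factor = ood_factor if ood else 1.0
        cfg = dataclasses.replace(
            base,
            anatomy_seed=anat_seed,
            noise_seed=noise_seed,
            body_axes=tuple(a * jit.uniform(0.92, 1.02) for a in base.body_axes),
            bone_center=tuple(c + jit.uniform(-0.04, 0.04) for c in base.bone_center),
            ptv_center=tuple(c + jit.uniform(-0.04, 0.04) for c in base.ptv_center),
            shading_amplitude=base.shading_amplitude * factor * jit.uniform(0.8, 1.2),
            streak_amplitude=base.streak_amplitude * factor * jit.uniform(0.8, 1.2),
            hu_offset=base.hu_offset * jit.uniform(0.8, 1.2),
            laplace_scales={k_: v * factor for k_, v in base.laplace_scales.items()},
        )
        sample = generate_phantom_pair(cfg)
        sample.ood = ood
        samples.append(sample)
    return samples
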