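"""Proxy photon dose engine and dose-uncertainty machinery.

The engine is a declared toy replacement for a clinical treatment-planning
system: HU is mapped to relative density rho = clip(1 + HU/1000, 0, 3),
radiological depth is accumulated along each beam (an exact cumulative sum for
axis-aligned beams, trilinear ray marching otherwise), and the per-beam dose
is a linear build-up ramp times an exponential falloff, restricted to a
cylindrical aperture around the target axis. Beams are summed and scaled once
so the PTV median dose on the planning image equals the prescription; the same
scale is reused for every ensemble member of a case, mirroring how a fixed
clinical plan is recomputed on plausible synthetic CTs.

On top of the engine: voxelwise dose ensemble statistics with
[D - 3 sigma_dose, D + 3 sigma_dose] bounds, cumulative DVHs and DVH
confidence bands, a 3-D local/global gamma index, and the subset-convergence
mean-absolute-error analysis of the dose standard-deviation map.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import map_coordinates

from .core import StructureSet, Volume, log_stage

_AXES = {
    (1, 0, 0): (0, +1), (-1, 0, 0): (0, -1),
    (0, 1, 0): (1, +1), (0, -1, 0): (1, -1),
    (0, 0, 1): (2, +1), (0, 0, -1): (2, -1),
}


@dataclasses.dataclass
class BeamConfig:
    """Beam geometry and depth-dose parameters of the proxy engine.

    ``directions`` are unit propagation vectors; the default is two opposed
    lateral beams. ``falloff_per_mm`` ~0.005 gives the ~0.5%/mm attenuation of
    a megavoltage photon beam in water; ``buildup_mm`` is the linear ramp to
    full dose. ``aperture_radius_mm`` bounds each beam to a cylinder around
    the axis through the PTV centroid.
    """

    directions: Tuple[Tuple[float, float, float], ...] = ((1.0, 0.0, 0.0), (-1.0, 0.0, 0.0))
    beam_weights: Optional[Tuple[float, ...]] = None
    aperture_radius_mm: float = 22.0
    mu_per_density: float = 1.0
    buildup_mm: float = 10.0
    falloff_per_mm: float = 0.005
    prescription_gy: float = 60.0
    step_mm: float = 1.0  # marching step for oblique beams

    def __post_init__(self) -> None:
        if len(self.directions) < 1:
            raise ValueError("need at least one beam")
        if self.mu_per_density < 0 or self.falloff_per_mm < 0:
            raise ValueError("attenuation and falloff must be non-negative")
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be positive")
        if self.beam_weights is not None and len(self.beam_weights) != len(self.directions):
            raise ValueError("one weight per beam required")


@dataclasses.dataclass
class DoseEnsembleStats:
    """Per-voxel mean, sigma_dose, and the +/- 3 sigma bound grids."""

    mean: Volume
    sigma: Volume          # sigma_dose, Gy
    lower: Volume          # max(nominal - 3 sigma, 0)
    upper: Volume          # nominal + 3 sigma
    n_members: int


@dataclasses.dataclass
class DVHCurve:
    """Cumulative dose-volume histogram for one structure."""

    edges: np.ndarray      # dose bin edges, Gy
    fraction: np.ndarray   # fraction of structure volume with dose >= edge
    label: str = ""


@dataclasses.dataclass
class GammaResult:
    """Gamma map (sentinel -1.0 at voxels below the dose threshold), pass rate
    in percent, and the criteria used."""

    gamma: Volume
    evaluated_mask: Volume
    pass_rate: float
    dd_percent: float
    dta_mm: float
    local: bool
    threshold_percent: float


def _density(image: Volume) -> np.ndarray:
    image.require_semantics("HU")
    return np.clip(1.0 + image.values.astype(np.float64) / 1000.0, 0.0, 3.0)


class DoseEngine:
    """Toy ray-marched photon engine with a plan/recompute split.

    ``plan`` computes dose on the planning image and freezes the global output
    scale so the PTV median equals the prescription; ``compute`` reuses that
    scale for any other image of the same case (ensemble members).
    """

    def __init__(self, beams: Optional[BeamConfig] = None):
        self.beams = beams or BeamConfig()
        self.scale_: Optional[float] = None
        self._ptv_centroid_mm: Optional[np.ndarray] = None

    # -- geometry helpers --------------------------------------------------
    def _physical_coords(self, vol: Volume) -> List[np.ndarray]:
        return [
            vol.origin[i] + np.arange(vol.shape[i]) * vol.spacing[i]
            for i in range(3)
        ]

    def _aperture(self, vol: Volume, direction: np.ndarray) -> np.ndarray:
        c = self._ptv_centroid_mm
        px, py, pz = np.meshgrid(*self._physical_coords(vol), indexing="ij")
        rel = np.stack([px - c[0], py - c[1], pz - c[2]])
        along = np.einsum("i,i...->...", direction, rel)
        perp2 = np.einsum("i...,i...->...", rel, rel) - along ** 2
        return perp2 <= self.beams.aperture_radius_mm ** 2

    def _radiological_depth(self, rho: np.ndarray, vol: Volume,
                            direction: np.ndarray) -> np.ndarray:
        key = tuple(int(round(d)) for d in direction)
        if key in _AXES and np.allclose(direction, key):
            axis, sign = _AXES[key]
            r = rho if sign > 0 else np.flip(rho, axis=axis)
            depth = np.cumsum(r, axis=axis) - 0.5 * r
            depth *= vol.spacing[axis]
            if sign < 0:
                depth = np.flip(depth, axis=axis)
            return depth * self.beams.mu_per_density
        # oblique: march upstream sampling density with trilinear interpolation
        step = self.beams.step_mm
        extent = np.linalg.norm(np.asarray(vol.shape) * np.asarray(vol.spacing))
        n_steps = int(np.ceil(extent / step))
        idx = np.indices(vol.shape, dtype=np.float64)
        step_vox = (direction * step) / np.asarray(vol.spacing)
        depth = np.zeros(vol.shape)
        coords = idx.reshape(3, -1).copy()
        upper = np.asarray(vol.shape, dtype=np.float64)[:, None] - 1.0
        for j in range(n_steps):
            coords_j = coords - step_vox[:, None] * (j + 0.5)
            outside = ((coords_j < 0) | (coords_j > upper)).any(axis=0)
            if outside.all():
                break
            vals = map_coordinates(rho, coords_j, order=1, mode="constant", cval=0.0)
            depth += vals.reshape(vol.shape) * step
        return depth * self.beams.mu_per_density

    def _raw_dose(self, image: Volume) -> np.ndarray:
        rho = _density(image)
        weights = self.beams.beam_weights or (1.0,) * len(self.beams.directions)
        total = np.zeros(image.shape)
        for direction, w in zip(self.beams.directions, weights):
            d = np.asarray(direction, dtype=np.float64)
            d = d / np.linalg.norm(d)
            depth = self._radiological_depth(rho, image, d)
            if self.beams.buildup_mm > 0:
                ramp = np.clip(depth / self.beams.buildup_mm, 0.0, 1.0)
            else:
                ramp = 1.0
            beam = ramp * np.exp(-self.beams.falloff_per_mm * depth)
            beam = beam * self._aperture(image, d)
            total += w * beam
        return total

    # -- public API --------------------------------------------------------
    def plan(self, image: Volume, structures: StructureSet) -> Volume:
        """Compute the planning dose and freeze the prescription scale."""
        if "ptv" not in structures:
            raise ValueError("structures must contain a 'ptv' mask")
        ptv = structures["ptv"].values > 0
        idx = np.argwhere(ptv).mean(axis=0)
        self._ptv_centroid_mm = np.asarray(image.origin) + idx * np.asarray(image.spacing)
        raw = self._raw_dose(image)
        med = float(np.median(raw[ptv]))
        if med <= 0:
            raise ValueError("aperture does not cover the PTV (zero median dose)")
        self.scale_ = self.beams.prescription_gy / med
        log_stage("dose_plan", None, self.beams)
        return image.like(raw * self.scale_, semantics="Gy")

    def compute(self, image: Volume) -> Volume:
        """Recompute dose on another image with the frozen plan scale."""
        if self.scale_ is None:
            raise RuntimeError("call plan() before compute()")
        return image.like(self._raw_dose(image) * self.scale_, semantics="Gy")


def compute_dose(image: Volume, beams: BeamConfig,
                 structures: StructureSet) -> Volume:
    """Plan and compute dose on one image (wrapper over :class:`DoseEngine`)."""
    return DoseEngine(beams).plan(image, structures)


def dose_ensemble_stats(doses: Sequence[Volume], nominal: Volume) -> DoseEnsembleStats:
    """sigma_dose over members (population divisor) and nominal -/+ 3 sigma bounds."""
    if len(doses) < 2:
        raise ValueError("need at least 2 dose members")
    for d in doses:
        nominal.check_geometry(d)
    stack = np.stack([d.values.astype(np.float64) for d in doses])
    mean = stack.mean(axis=0)
    sigma = np.sqrt(np.mean((stack - mean) ** 2, axis=0))
    nom = nominal.values.astype(np.float64)
    lower = np.maximum(nom - 3.0 * sigma, 0.0)
    upper = nom + 3.0 * sigma
    return DoseEnsembleStats(
        mean=nominal.like(mean, semantics="Gy"),
        sigma=nominal.like(sigma, semantics="Gy"),
        lower=nominal.like(lower, semantics="Gy"),
        upper=nominal.like(upper, semantics="Gy"),
        n_members=len(doses),
    )


def dvh(dose: Volume, mask: Volume, bin_width: float = 0.01,
        label: str = "", edges: Optional[np.ndarray] = None) -> DVHCurve:
    """Cumulative DVH: fraction of in-mask voxels with dose >= each edge."""
    dose.check_geometry(mask)
    mask.require_semantics("mask")
    sel = mask.values > 0
    if not sel.any():
        raise ValueError("empty structure mask")
    vals = np.sort(dose.values[sel].astype(np.float64))
    if edges is None:
        edges = np.arange(0.0, vals[-1] + 2 * bin_width, bin_width)
    frac = 1.0 - np.searchsorted(vals, edges, side="left") / vals.size
    return DVHCurve(edges=np.asarray(edges, dtype=np.float64), fraction=frac, label=label)


def dvh_band(lower: Volume, nominal: Volume, upper: Volume, mask: Volume,
             bin_width: float = 0.01, label: str = ""
             ) -> Tuple[DVHCurve, DVHCurve, DVHCurve]:
    """DVHs of lower/nominal/upper grids on shared edges (an ordered band)."""
    for v in (lower, upper, mask):
        nominal.check_geometry(v)
    lo = lower.values.astype(np.float64)
    no = nominal.values.astype(np.float64)
    up = upper.values.astype(np.float64)
    if np.any(lo > no + 1e-9) or np.any(no > up + 1e-9):
        raise ValueError("bound ordering violated: need lower <= nominal <= upper")
    top = float(up[mask.values > 0].max())
    edges = np.arange(0.0, top + 2 * bin_width, bin_width)
    return (
        dvh(lower, mask, bin_width, label=f"{label}:lower", edges=edges),
        dvh(nominal, mask, bin_width, label=f"{label}:nominal", edges=edges),
        dvh(upper, mask, bin_width, label=f"{label}:upper", edges=edges),
    )


def gamma_index(reference: Volume, evaluated: Volume, dd_percent: float = 1.0,
                dta_mm: float = 1.0, local: bool = True,
                threshold_percent: float = 10.0, search_factor: float = 3.0,
                step_fraction: float = 0.1) -> GammaResult:
    """3-D gamma index with sub-voxel spatial search.

    For each reference voxel at or above ``threshold_percent`` of the
    reference maximum, gamma is the minimum over evaluated positions within
    ``search_factor * dta`` (step ``dta * step_fraction``, trilinear
    interpolation) of sqrt((dose diff / dd_abs)^2 + (distance / dta)^2), with
    dd_abs local (per-voxel reference dose) or global (reference maximum).
    Offsets are visited in order of increasing distance with exact pruning, so
    the result equals a dense exhaustive search. Candidate positions outside
    the evaluated grid are excluded.
    """
    reference.check_geometry(evaluated)
    if dd_percent <= 0 or dta_mm <= 0:
        raise ValueError("dd and dta must be positive")
    ref = reference.values.astype(np.float64)
    ev = evaluated.values.astype(np.float64)
    ref_max = float(ref.max())
    if ref_max <= 0:
        raise ValueError("reference dose has no positive voxels to evaluate")
    sel = ref >= threshold_percent / 100.0 * ref_max
    if not sel.any():
        raise ValueError("no voxels at or above the dose threshold")
    refv = ref[sel]
    dd_abs = dd_percent / 100.0 * (np.abs(refv) if local
                                   else np.full_like(refv, ref_max))

    # physical offsets within the search sphere, nearest first
    step = dta_mm * step_fraction
    n_steps = int(np.ceil(search_factor * dta_mm / step))
    ax = np.arange(-n_steps, n_steps + 1) * step
    off = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    dist = np.linalg.norm(off, axis=1)
    keep = dist <= search_factor * dta_mm + 1e-9
    off, dist = off[keep], dist[keep]
    order = np.argsort(dist, kind="stable")
    off, dist = off[order], dist[order]

    coords0 = np.argwhere(sel).T.astype(np.float64)
    spacing = np.asarray(reference.spacing)
    cval = abs(ref_max) * 1e6 + 1e6
    gamma2 = np.full(refv.shape, np.inf)
    for r, d in zip(off, dist):
        dist_term = (d / dta_mm) ** 2
        active = gamma2 > dist_term
        if not active.any():
            break
        coords = coords0[:, active] + (r / spacing)[:, None]
        vals = map_coordinates(ev, coords, order=1, mode="constant", cval=cval)
        cand = ((vals - refv[active]) / dd_abs[active]) ** 2 + dist_term
        gamma2[active] = np.minimum(gamma2[active], cand)

    gamma_sel = np.sqrt(gamma2)
    gmap = np.full(reference.shape, -1.0)
    gmap[sel] = gamma_sel
    pass_rate = 100.0 * float(np.mean(gamma_sel <= 1.0))
    return GammaResult(
        gamma=reference.like(gmap, semantics="scale"),
        evaluated_mask=reference.like(sel.astype(np.float32), semantics="mask"),
        pass_rate=pass_rate,
        dd_percent=dd_percent, dta_mm=dta_mm, local=local,
        threshold_percent=threshold_percent,
    )


def subset_variance_mae(members: Sequence[Volume], n: int, repeats: int = 20,
                        seed: int = 0, mask: Optional[Volume] = None) -> float:
    """Mean absolute difference (cGy) between subset and full-set sigma_dose maps.

    For each repeat, ``n`` members are drawn without replacement, their
    voxelwise dose standard deviation is compared with the full-ensemble map,
    and the absolute differences are averaged over in-mask voxels; the result
    is the average over repeats, in cGy.
    """
    m = len(members)
    if not 2 <= n < m:
        raise ValueError(f"need 2 <= n < {m}, got n={n}")
    stack = np.stack([v.values.astype(np.float64) for v in members])
    sel = np.ones(members[0].shape, dtype=bool) if mask is None else mask.values > 0
    full = np.std(stack, axis=0)[sel]
    rng = np.random.default_rng(seed)
    maes = []
    for _ in range(repeats):
        idx = rng.choice(m, size=n, replace=False)
        sub = np.std(stack[idx], axis=0)[sel]
        maes.append(float(np.mean(np.abs(sub - full))))
    return 100.0 * float(np.mean(maes))
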