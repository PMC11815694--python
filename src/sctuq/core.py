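"""Core data model: volumes, structure sets, NIfTI I/O, seeded RNG plumbing.

The internal axis convention is ``(x, y, z)`` with 0-based indexing; the NIfTI
affine is reduced to per-axis spacing plus an origin (orthonormal, axis-aligned
orientation assumed). Voxel values are stored as float32 — at least 32-bit per
the data contract — while all arithmetic elsewhere in the package is carried
out in float64, which makes file round trips and the HU normalisation round
trip voxel-exact on stored values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import nibabel as nib
import numpy as np

logger = logging.getLogger("sctuq")

#: Recognised value semantics for a :class:`Volume`.
SEMANTICS = ("HU", "normalized", "Gy", "scale", "variance", "mask")


class GeometryError(ValueError):
    """Grids disagree in shape, spacing or origin, or an image is not 3-D."""


class SemanticsError(ValueError):
    """An operation received a volume with the wrong value semantics."""


def _as_tuple3(x: Sequence[float]) -> Tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise GeometryError(f"expected 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclasses.dataclass
class Volume:
    """A 3-D scalar grid with voxel spacing (mm), origin (mm) and semantics.

    ``semantics`` declares what the values mean: Hounsfield units, normalised
    intensities (HU/1000), dose in Gy, a noise-scale map, a variance map, or a
    binary mask (values exactly 0/1).
    """

    values: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    semantics: str = "HU"

    def __post_init__(self) -> None:
        # HU and masks are stored as float32 (with arithmetic in float64 this
        # makes the /1000 <-> *1000 round trip reproduce stored HU voxels
        # bit-exactly); derived maps keep full float64 precision
        dtype = np.float32 if self.semantics in ("HU", "mask") else np.float64
        self.values = np.asarray(self.values, dtype=dtype)
        if self.values.ndim != 3:
            raise GeometryError(f"volume must be 3-D, got ndim={self.values.ndim}")
        self.spacing = _as_tuple3(self.spacing)
        self.origin = _as_tuple3(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        if self.semantics not in SEMANTICS:
            raise SemanticsError(f"unknown semantics {self.semantics!r}; expected one of {SEMANTICS}")
        if not np.all(np.isfinite(self.values)):
            # Sentinel values (e.g. the gamma map's -1 at unevaluated voxels)
            # are finite by construction; NaN/Inf are always a bug.
            raise ValueError("volume values must be finite")
        if self.semantics == "mask":
            vals = np.unique(self.values)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError("mask volumes must contain only 0 and 1")

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def like(self, values: np.ndarray, semantics: str | None = None) -> "Volume":
        """A new volume on this grid with different values (and semantics)."""
        return Volume(values, self.spacing, self.origin, semantics or self.semantics)

    def same_geometry(self, other: "Volume", atol: float = 1e-4) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def check_geometry(self, other: "Volume") -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                f"geometry mismatch: {self.shape}/{self.spacing}/{self.origin} vs "
                f"{other.shape}/{other.spacing}/{other.origin}"
            )

    def require_semantics(self, *allowed: str) -> None:
        if self.semantics not in allowed:
            raise SemanticsError(f"expected semantics in {allowed}, got {self.semantics!r}")


def read_volume(path: str | os.PathLike, semantics: str | None = None) -> Volume:
    """Read a NIfTI file into a :class:`Volume`.

    Spacing and origin are taken from the header; the value semantics is
    recovered from the ``descrip`` field when present (written by
    :func:`write_volume`), else defaults to ``"HU"`` or the ``semantics``
    argument.
    """
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise GeometryError(f"expected a 3-D NIfTI image, got ndim={data.ndim}")
    affine = img.affine
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in affine[:3, 3])
    sem = semantics
    if sem is None:
        descrip = bytes(img.header["descrip"].tobytes()).split(b"\x00")[0].decode(errors="ignore")
        sem = descrip.split("semantics=", 1)[1] if "semantics=" in descrip else "HU"
        if sem not in SEMANTICS:
            sem = "HU"
    return Volume(data, spacing, origin, sem)


def write_volume(volume: Volume, path: str | os.PathLike) -> None:
    """Write a :class:`Volume` as NIfTI (.nii/.nii.gz); round trip is voxel-exact."""
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.values, affine)  # dtype preserved (f32/f64)
    img.header["descrip"] = f"semantics={volume.semantics}".encode()
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


@dataclasses.dataclass
class StructureSet:
    """Named binary masks (external, ptv, oar_*, bone, air) on one grid."""

    masks: Dict[str, Volume]

    def __post_init__(self) -> None:
        if "external" not in self.masks:
            raise ValueError("a StructureSet requires an 'external' mask")
        ref = self.masks["external"]
        for label, m in self.masks.items():
            m.require_semantics("mask")
            ref.check_geometry(m)
        if not np.any(ref.values > 0):
            raise ValueError("external mask is empty")

    def __getitem__(self, label: str) -> Volume:
        return self.masks[label]

    def __contains__(self, label: str) -> bool:
        return label in self.masks

    @property
    def labels(self) -> Tuple[str, ...]:
        return tuple(self.masks)

    def write(self, directory: str | os.PathLike) -> None:
        """One NIfTI per mask plus a manifest listing label -> filename."""
        directory = str(directory)
        os.makedirs(directory, exist_ok=True)
        manifest = {}
        for label, m in self.masks.items():
            fname = f"{label}.nii.gz"
            write_volume(m, os.path.join(directory, fname))
            manifest[label] = fname
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def read(cls, directory: str | os.PathLike) -> "StructureSet":
        directory = str(directory)
        with open(os.path.join(directory, "manifest.json")) as fh:
            manifest = json.load(fh)
        masks = {
            label: read_volume(os.path.join(directory, fname), semantics="mask")
            for label, fname in manifest.items()
        }
        return cls(masks)


# -- seeded RNG and config plumbing ---------------------------------------

def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed."""
    state = np.random.SeedSequence(int(seed)).generate_state(n, dtype=np.uint32)
    return [int(s >> 1) for s in state]


def config_digest(config: Mapping | Iterable | dataclasses.dataclass) -> str:
    """Short stable hash of a configuration object, for logging."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha1(payload).hexdigest()[:10]


def log_stage(stage: str, seed: int | None = None, config=None) -> None:
    """Log a pipeline stage with its seed and config hash (reproducibility trail)."""
    digest = config_digest(config) if config is not None else "-"
    logger.info("stage=%s seed=%s config=%s", stage, seed, digest)
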