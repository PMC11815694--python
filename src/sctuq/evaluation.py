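"""Image-quality and uncertainty-quality metrics.

MAE / ME / PSNR inside the external body, Pearson correlation between
uncertainty and absolute-error maps, a voxel-shift sensitivity probe of that
correlation, and Fisher's Z comparison of two correlation coefficients.

PSNR uses a fixed 4000 HU data range (the clip span) so values are comparable
across cases; identical images report an infinite PSNR sentinel.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import Volume

PSNR_RANGE_HU = 4000.0


@dataclasses.dataclass
class MetricsReport:
    """One evaluation row for a case."""

    case: str
    mae_hu: float
    me_hu: float
    psnr_db: float
    pcc_uncalibrated: float = np.nan
    pcc_calibrated: float = np.nan
    pcc_shifted: Optional[Dict[str, float]] = None
    n_voxels: int = 0
    ood: bool = False


def image_metrics(sct: Volume, ct: Volume, mask: Volume) -> Tuple[float, float, float]:
    """(MAE, ME, PSNR) between sCT and CT over in-mask voxels, HU / HU / dB."""
    sct.check_geometry(ct)
    sct.check_geometry(mask)
    sel = mask.values > 0
    if not sel.any():
        raise ValueError("empty mask")
    diff = sct.values[sel].astype(np.float64) - ct.values[sel].astype(np.float64)
    mae = float(np.mean(np.abs(diff)))
    me = float(np.mean(diff))
    mse = float(np.mean(diff ** 2))
    psnr = np.inf if mse == 0 else 10.0 * np.log10(PSNR_RANGE_HU ** 2 / mse)
    return mae, me, float(psnr)


def uncertainty_error_pcc(sigma: Volume, error: Volume, mask: Volume) -> float:
    """Pearson correlation between uncertainty and |CT - sCT| over the mask."""
    sigma.check_geometry(error)
    sigma.check_geometry(mask)
    sel = mask.values > 0
    x = sigma.values[sel].astype(np.float64)
    y = error.values[sel].astype(np.float64)
    if x.size < 3:
        raise ValueError("need at least 3 in-mask voxels")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance in a map")
    return float(stats.pearsonr(x, y)[0])


def shift_sensitivity(ct: Volume, sct: Volume, sigma: Volume, mask: Volume,
                      shift_voxels: int = 2) -> Dict[str, float]:
    """PCC(sigma, |CT_shifted - sCT|) after translating CT along each axis.

    The CT is rolled by ``shift_voxels`` (integer roll, no interpolation);
    voxels wrapped across the moving edge are dropped from the mask. A shift
    of 0 is allowed as a control and reproduces the unshifted PCC.
    """
    if shift_voxels < 0:
        raise ValueError("shift must be >= 0")
    out = {}
    for axis, name in enumerate("xyz"):
        if shift_voxels >= ct.shape[axis]:
            raise ValueError(f"shift {shift_voxels} >= grid extent on axis {name}")
        ct_s = np.roll(ct.values.astype(np.float64), shift_voxels, axis=axis)
        valid = mask.values > 0
        if shift_voxels > 0:
            edge = [slice(None)] * 3
            edge[axis] = slice(0, shift_voxels)
            valid = valid.copy()
            valid[tuple(edge)] = False
        err = np.abs(ct_s - sct.values.astype(np.float64))
        out[name] = uncertainty_error_pcc(
            sigma,
            sigma.like(err, semantics="scale"),
            sigma.like(valid.astype(np.float32), semantics="mask"),
        )
    return out


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> Tuple[float, float]:
    """Fisher's Z test comparing two independent Pearson correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); returns (z,
    two-tailed p). The caller compares p with its significance level.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1.0:
            raise ValueError("|r| must be < 1")
        if n <= 3:
            raise ValueError("need n > 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def cohort_report(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    """Assemble per-case reports into one DataFrame (CSV-ready)."""
    rows = []
    for r in reports:
        row = dataclasses.asdict(r)
        shifted = row.pop("pcc_shifted") or {}
        for name, v in shifted.items():
            row[f"pcc_shift_{name}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
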