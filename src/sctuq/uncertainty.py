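"""Epistemic uncertainty by Monte-Carlo dropout, total-uncertainty
combination, and linear-regression calibration.

MC dropout keeps dropout active at inference (it is off during training) and
treats the T stochastic forward passes as samples from the approximate weight
posterior. The model variance is the population variance over the T passes
(divisor T). Aleatoric and epistemic parts combine quadratically,
sigma_tot = sqrt(sigma_data^2 + sigma_model^2), and a pooled ordinary
least-squares fit of observed |CT - sCT| on predicted sigma aligns the
uncertainty scale with the actual error scale.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.linear_model import LinearRegression

from .core import Volume, log_stage, spawn_seeds
from .translation import GeneratorOutput, HeteroscedasticTranslator


@dataclasses.dataclass
class McdConfig:
    """T stochastic passes at inference dropout rate phi (paper: T=50, phi=0.3)."""

    T: int = 50
    dropout: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ValueError("T must be >= 2")
        if not (0.0 < self.dropout < 1.0):
            raise ValueError("dropout must be in (0, 1)")


@dataclasses.dataclass
class McdEnsemble:
    """T stochastic outputs, their voxelwise mean, and per-pass log-scale maps."""

    samples: List[Volume]          # sct samples, normalized units
    mean: Volume
    log_scale_samples: List[Volume]

    @property
    def T(self) -> int:
        return len(self.samples)


@dataclasses.dataclass
class UncertaintyMaps:
    """sigma_data / sigma_model / sigma_total maps (standard-deviation units)."""

    sigma_data: Volume
    sigma_model: Volume
    sigma_total: Volume
    calibrated: bool = False


def mcd_sample(model: HeteroscedasticTranslator, cbct: Volume,
               config: Optional[McdConfig] = None) -> McdEnsemble:
    """Run T seeded forward passes with dropout injected at inference."""
    config = config or McdConfig()
    log_stage("mcd", config.seed, config)
    seeds = spawn_seeds(config.seed, config.T)
    samples, log_scales = [], []
    for s in seeds:
        out: GeneratorOutput = model.stochastic_predict(
            cbct, dropout=config.dropout, rng=np.random.default_rng(s)
        )
        samples.append(out.sct)
        log_scales.append(out.log_scale)
    stack = np.stack([v.values.astype(np.float64) for v in samples])
    mean = samples[0].like(stack.mean(axis=0), semantics="normalized")
    return McdEnsemble(samples=samples, mean=mean, log_scale_samples=log_scales)


def model_variance(ensemble: McdEnsemble) -> Volume:
    """Voxelwise population variance over the T passes (divisor T)."""
    if ensemble.T < 2:
        raise ValueError("need at least 2 samples")
    ref = ensemble.samples[0]
    for v in ensemble.samples[1:]:
        ref.check_geometry(v)
    stack = np.stack([v.values.astype(np.float64) for v in ensemble.samples])
    var = np.mean((stack - stack.mean(axis=0)) ** 2, axis=0)
    return ref.like(var, semantics="variance")


def sigma_data_from_ensemble(ensemble: McdEnsemble) -> Volume:
    """Average exp(log-scale) over the T passes: one aleatoric scale map.

    The per-pass aleatoric maps differ only through dropout; averaging them is
    the lowest-variance unbiased reduction to a single map.
    """
    stack = np.stack(
        [np.exp(v.values.astype(np.float64)) for v in ensemble.log_scale_samples]
    )
    return ensemble.samples[0].like(stack.mean(axis=0), semantics="scale")


def combine_uncertainty(sigma_data: Volume, sigma_model: Volume) -> Volume:
    """Quadratic combination: sigma_tot = sqrt(sigma_data^2 + sigma_model^2)."""
    sigma_data.check_geometry(sigma_model)
    a = sigma_data.values.astype(np.float64)
    b = sigma_model.values.astype(np.float64)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("uncertainty maps must be non-negative")
    return sigma_data.like(np.sqrt(a * a + b * b), semantics="scale")


def uncertainty_maps(ensemble: McdEnsemble, units: str = "HU") -> UncertaintyMaps:
    """Assemble sigma_data / sigma_model / sigma_tot from an MCD ensemble.

    ``units="HU"`` scales the normalized-unit maps by 1000 for reporting.
    """
    factor = 1000.0 if units == "HU" else 1.0
    sd = sigma_data_from_ensemble(ensemble)
    sm_var = model_variance(ensemble)
    sd = sd.like(sd.values.astype(np.float64) * factor, semantics="scale")
    sm = sm_var.like(np.sqrt(sm_var.values.astype(np.float64)) * factor, semantics="scale")
    return UncertaintyMaps(
        sigma_data=sd, sigma_model=sm, sigma_total=combine_uncertainty(sd, sm)
    )


def normal_interval_coverage(k: float = 3.0, n: int = 4_000_000, seed: int = 0) -> float:
    """Monte-Carlo percentage of standard-normal draws within +/- k sigma.

    Documents the coverage claim behind the [D - 3 sigma, D + 3 sigma] dose
    bounds (99.7% for k=3 under normality).
    """
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal(int(n))
    return 100.0 * float(np.mean(np.abs(draws) <= k))


class UncertaintyCalibrator(BaseEstimator):
    """Affine calibration of predicted uncertainty against observed error.

    Ordinary least squares of pooled in-mask |CT - sCT| on predicted sigma,
    subsampled to ``max_pairs`` voxel pairs (seeded). ``transform`` applies
    ``max(slope * sigma + intercept, floor)``.

    Fitted attributes: ``slope_``, ``intercept_``, ``n_voxels_``,
    ``residual_var_``.
    """

    def __init__(self, floor: float = 0.0, max_pairs: int = 1_000_000, seed: int = 0):
        self.floor = floor
        self.max_pairs = max_pairs
        self.seed = seed

    def fit(self, sigmas: Sequence[Volume], errors: Sequence[Volume],
            masks: Sequence[Volume]) -> "UncertaintyCalibrator":
        if not (len(sigmas) == len(errors) == len(masks)) or len(sigmas) == 0:
            raise ValueError("need matched, non-empty sequences")
        xs, ys = [], []
        for s, e, m in zip(sigmas, errors, masks):
            s.check_geometry(e)
            s.check_geometry(m)
            sel = m.values > 0
            xs.append(s.values[sel].astype(np.float64))
            ys.append(e.values[sel].astype(np.float64))
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        if x.size < 10:
            raise ValueError(f"too few pooled voxels ({x.size}) to calibrate")
        if x.size > self.max_pairs:
            idx = np.random.default_rng(self.seed).choice(
                x.size, size=self.max_pairs, replace=False
            )
            x, y = x[idx], y[idx]
        reg = LinearRegression().fit(x[:, None], y)
        self.slope_ = float(reg.coef_[0])
        self.intercept_ = float(reg.intercept_)
        self.n_voxels_ = int(x.size)
        self.residual_var_ = float(np.var(y - reg.predict(x[:, None])))
        log_stage("calibration", self.seed, self.get_params())
        return self

    def transform(self, sigma_total: Volume) -> Volume:
        if not hasattr(self, "slope_"):
            raise RuntimeError("calibrator is not fitted; call fit() first")
        vals = np.maximum(
            self.slope_ * sigma_total.values.astype(np.float64) + self.intercept_,
            self.floor,
        )
        return sigma_total.like(vals, semantics="scale")

    # -- persistence -------------------------------------------------------
    def save(self, path: str | os.PathLike) -> None:
        payload = {
            "slope": self.slope_, "intercept": self.intercept_,
            "floor": self.floor, "n_voxels": self.n_voxels_,
            "residual_var": self.residual_var_,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "UncertaintyCalibrator":
        with open(path) as fh:
            payload = json.load(fh)
        cal = cls(floor=payload["floor"])
        cal.slope_ = payload["slope"]
        cal.intercept_ = payload["intercept"]
        cal.n_voxels_ = payload["n_voxels"]
        cal.residual_var_ = payload["residual_var"]
        return cal


def fit_calibration(sigmas: Sequence[Volume], errors: Sequence[Volume],
                    masks: Sequence[Volume], floor: float = 0.0,
                    seed: int = 0) -> UncertaintyCalibrator:
    """OLS calibration of uncertainty vs absolute error (wrapper)."""
    return UncertaintyCalibrator(floor=floor, seed=seed).fit(sigmas, errors, masks)


def apply_calibration(model: UncertaintyCalibrator, sigma_total: Volume) -> Volume:
    """Apply a fitted calibration to a sigma map (wrapper)."""
    return model.transform(sigma_total)
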