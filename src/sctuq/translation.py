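"""Two-channel CBCT-to-sCT translation with a heteroscedastic Laplacian loss.

The generator predicts the translated image and, in a second channel, the
per-voxel natural log of the aleatoric noise scale sigma_data (normalised
units). Training minimises

    w_rec * (1/N) sum |t_i - s_i|
  + w_unc * (1/N) sum [ |t_i - s_i| / sigma_i + log sigma_i ]
  (+ w_adv * least-squares adversarial term, off by default)

over in-mask voxels, with sigma_i = exp(log-scale_i) floored at
``sigma_floor`` for 1/sigma stability. The per-voxel optimum of the
uncertainty term is sigma* = |t - s|, so the scale channel learns the local
magnitude of the irreducible residual.

The estimator follows scikit-learn conventions (constructor params,
``fit``/``predict``, trailing-underscore fitted attributes); ``train`` and
``predict`` module functions are thin wrappers over it.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.base import BaseEstimator

from ._nets import Adam, PatchDiscriminator, UNet
from .core import GeometryError, Volume, log_stage
from .phantom import PairedSample
from .preprocess import clip_and_normalize

ArrayLike = Union[Volume, np.ndarray]


@dataclasses.dataclass
class GeneratorOutput:
    """One forward pass: predicted image and log aleatoric-scale map."""

    sct: Volume        # normalized units
    log_scale: Volume  # log of sigma_data in normalized units, semantics="scale"

    def sigma_data(self) -> Volume:
        """exp(log scale): the aleatoric scale map in normalized units."""
        return self.log_scale.like(
            np.exp(self.log_scale.values.astype(np.float64)), semantics="scale"
        )


@dataclasses.dataclass
class TrainConfig:
    """Optimiser and loss settings (Adam, batch 1, base lr 1e-3 with linear
    decay; the clinical reference configuration used 2e-4 for a much larger
    backbone)."""

    epochs: int = 40
    lr: float = 1e-3
    batch_size: int = 1
    dropout: float = 0.0          # training-time dropout; MC dropout is applied at inference
    w_rec: float = 1.0
    w_unc: float = 1.0
    w_adv: float = 0.0
    seed: int = 0
    width: int = 16
    depth: int = 2
    mode: str = "2d"              # "2d" slice training or "3d"
    slice_axis: int = 2
    sigma_floor: float = 1e-4
    grad_clip: float = 5.0
    loss_region: str = "external"  # "external" or "all"
    augment: bool = True           # random flip/rotation of 2D slices

    def __post_init__(self) -> None:
        if min(self.w_rec, self.w_unc, self.w_adv) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.mode not in ("2d", "3d"):
            raise ValueError("mode must be '2d' or '3d'")


def _values(x: ArrayLike) -> np.ndarray:
    return np.asarray(x.values if isinstance(x, Volume) else x, dtype=np.float64)


def laplacian_nll(output: GeneratorOutput, target: Volume, mask: Volume,
                  sigma_floor: float = 1e-4) -> float:
    """Masked Laplacian negative log-likelihood (additive constant dropped).

    ``(1/N) sum_i [ |target_i - sct_i| / sigma_i + log sigma_i ]`` over the N
    in-mask voxels, sigma = exp(log scale) floored at ``sigma_floor``.
    """
    for v in (target, mask):
        output.sct.check_geometry(v)
    m = mask.values > 0
    n = int(m.sum())
    if n == 0:
        raise ValueError("mask is empty")
    r = _values(target)[m] - _values(output.sct)[m]
    sigma = np.maximum(np.exp(_values(output.log_scale)[m]), sigma_floor)
    return float(np.mean(np.abs(r) / sigma + np.log(sigma)))


class HeteroscedasticTranslator(BaseEstimator):
    """Compact U-Net translator with a log-scale uncertainty channel.

    Parameters mirror :class:`TrainConfig`. Fitted attributes: ``net_`` (the
    numpy U-Net), ``loss_history_`` (mean total loss per epoch), ``n_epochs_``.
    """

    def __init__(self, epochs: int = 40, lr: float = 1e-3, batch_size: int = 1,
                 dropout: float = 0.0, w_rec: float = 1.0, w_unc: float = 1.0,
                 w_adv: float = 0.0, seed: int = 0, width: int = 16,
                 depth: int = 2, mode: str = "2d", slice_axis: int = 2,
                 sigma_floor: float = 1e-4, grad_clip: float = 5.0,
                 loss_region: str = "external", augment: bool = True):
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.dropout = dropout
        self.w_rec = w_rec
        self.w_unc = w_unc
        self.w_adv = w_adv
        self.seed = seed
        self.width = width
        self.depth = depth
        self.mode = mode
        self.slice_axis = slice_axis
        self.sigma_floor = sigma_floor
        self.grad_clip = grad_clip
        self.loss_region = loss_region
        self.augment = augment

    # -- internal helpers --------------------------------------------------
    def _nd(self) -> int:
        return 2 if self.mode == "2d" else 3

    def _input_channels(self, values: np.ndarray) -> np.ndarray:
        """Stack the volume with its slice-axis mean projection.

        The projection averages voxel-scale texture and noise away while
        slice-constant artifact fields (cupping, streaks, offset) survive at
        full strength, giving the decoder a clean view of what to subtract.
        """
        proj = values.mean(axis=self.slice_axis, keepdims=True)
        return np.stack([values, np.broadcast_to(proj, values.shape)], axis=0)

    def _to_items(self, X, y, masks) -> List[Tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Split volumes into training items: (input, target, mask) arrays."""
        items = []
        for i, (xv, tv) in enumerate(zip(X, y)):
            xa, ta = _values(xv), _values(tv)
            if xa.shape != ta.shape:
                raise GeometryError("input/target shape mismatch")
            ma = np.ones_like(xa) if masks is None else _values(masks[i])
            ch = self._input_channels(xa)
            if self.mode == "2d":
                ax = self.slice_axis
                for k in range(xa.shape[ax]):
                    sl = [slice(None), slice(None), slice(None)]
                    sl[ax] = k
                    s = (slice(None),) + tuple(sl)
                    t = tuple(sl)
                    if ma[t].sum() > 0:
                        items.append((ch[s], ta[t], ma[t]))
            else:
                if ma.sum() > 0:
                    items.append((ch, ta, ma))
        if not items:
            raise ValueError("no training items with non-empty masks")
        return items

    def _augment(self, item, rng: np.random.Generator):
        """Random flip / right-angle rotation of one 2D training item.

        Multiplies the diversity of artifact patterns (streak angles and
        offsets) seen in training, which is what lets streak removal
        generalise to unseen phantoms from a small cohort.
        """
        x, t, m = item
        if x.ndim != 3:  # 3D mode items are left untouched
            return item
        k = int(rng.integers(4)) if x.shape[-2] == x.shape[-1] else 0
        flip = bool(rng.integers(2))
        if k:
            x = np.rot90(x, k, axes=(-2, -1))
            t = np.rot90(t, k, axes=(-2, -1))
            m = np.rot90(m, k, axes=(-2, -1))
        if flip:
            x, t, m = x[..., ::-1], t[..., ::-1], m[..., ::-1]
        return np.ascontiguousarray(x), np.ascontiguousarray(t), np.ascontiguousarray(m)

    def _loss_and_grad(self, out: np.ndarray, target: np.ndarray, mask: np.ndarray
                       ) -> Tuple[float, np.ndarray]:
        """Total supervised loss and its gradient w.r.t. the network output."""
        s, ls = out[:, 0], out[:, 1]
        m = mask > 0
        n = int(m.sum())
        ls_eff = np.clip(ls, np.log(self.sigma_floor), 12.0)
        sigma = np.exp(ls_eff)
        r = target - s
        absr = np.abs(r)
        nll = float(np.sum((absr / sigma + ls_eff)[m]) / n)
        rec = float(np.sum(absr[m]) / n)
        grad = np.zeros_like(out)
        sign = np.sign(r)
        gs = -(self.w_rec + self.w_unc / sigma) * sign / n
        gl = self.w_unc * (1.0 - absr / sigma) / n
        active = (ls > np.log(self.sigma_floor)) & (ls < 12.0)
        grad[:, 0] = np.where(m, gs, 0.0)
        grad[:, 1] = np.where(m & active, gl, 0.0)
        return self.w_rec * rec + self.w_unc * nll, grad

    def _adv_step(self, fake: np.ndarray, real: np.ndarray) -> np.ndarray:
        """One LSGAN discriminator update; returns dL_adv/d(fake)."""
        d = self.disc_
        # discriminator: 0.5[(D(real)-1)^2 + D(fake)^2]
        saved = []
        score_r = d.forward(real)
        d.backward(score_r - 1.0)
        saved = [(layer.dW.copy(), layer.db.copy()) for layer in d.layers()]
        score_f = d.forward(fake)
        d.backward(score_f)
        for layer, (dW, db) in zip(d.layers(), saved):
            layer.dW += dW
            layer.db += db
        self.disc_opt_.step()
        # generator term: (D(fake)-1)^2 against the updated critic
        score_f = d.forward(fake)
        return d.backward(2.0 * (score_f - 1.0))

    # -- estimator API -----------------------------------------------------
    def fit(self, X: Sequence[ArrayLike], y: Sequence[ArrayLike],
            masks: Optional[Sequence[ArrayLike]] = None) -> "HeteroscedasticTranslator":
        """Train on paired (input, target) volumes in normalized units."""
        if len(X) == 0 or len(X) != len(y):
            raise ValueError("need equal, non-empty input/target sequences")
        items = self._to_items(X, y, masks)
        nd = self._nd()
        self.net_ = UNet(in_ch=2, out_ch=2, width=self.width, nd=nd,
                         depth=self.depth, seed=self.seed)
        opt = Adam(self.net_.layers(), lr=self.lr, grad_clip=self.grad_clip)
        if self.w_adv > 0:
            self.disc_ = PatchDiscriminator(in_ch=1, nd=nd, seed=self.seed + 1)
            self.disc_opt_ = Adam(self.disc_.layers(), lr=self.lr)
        rng = np.random.default_rng(self.seed)
        log_stage("train", self.seed, self.get_params())
        history = []
        bs = max(1, int(self.batch_size))
        for epoch in range(self.epochs):
            # linear decay to 20% of the base rate: lets the scale channel
            # settle to the local residual magnitude late in training
            frac = epoch / max(1, self.epochs - 1)
            opt.lr = self.lr * (1.0 - 0.8 * frac)
            order = rng.permutation(len(items))
            losses = []
            for start in range(0, len(order), bs):
                batch = [self._augment(items[j], rng) if self.augment else items[j]
                         for j in order[start:start + bs]]
                x = np.stack([b[0] for b in batch])
                t = np.stack([b[1] for b in batch])
                m = np.stack([b[2] for b in batch])
                drop_rng = rng if self.dropout > 0 else None
                out = self.net_.forward(x, dropout=self.dropout, rng=drop_rng)
                loss, grad = self._loss_and_grad(out, t, m)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, step {start // bs}: {loss}"
                    )
                if self.w_adv > 0:
                    dadv = self._adv_step(out[:, 0:1], t[:, None])
                    grad[:, 0:1] += self.w_adv * dadv
                self.net_.backward(grad)
                opt.step()
                losses.append(loss)
            history.append(float(np.mean(losses)))
        self.loss_history_ = history
        self.n_epochs_ = self.epochs
        return self

    def _forward_volume(self, values: np.ndarray, dropout: float = 0.0,
                        rng: Optional[np.random.Generator] = None
                        ) -> Tuple[np.ndarray, np.ndarray]:
        ch = self._input_channels(values)
        if self.mode == "2d":
            x = np.moveaxis(ch, 1 + self.slice_axis, 0)
            # chunk the slice batch to keep im2col buffers small
            chunks = [
                self.net_.forward(x[i:i + 2], dropout=dropout, rng=rng)
                for i in range(0, x.shape[0], 2)
            ]
            out = np.concatenate(chunks, axis=0)
            sct = np.moveaxis(out[:, 0], 0, self.slice_axis)
            ls = np.moveaxis(out[:, 1], 0, self.slice_axis)
        else:
            out = self.net_.forward(ch[None], dropout=dropout, rng=rng)
            sct, ls = out[0, 0], out[0, 1]
        return sct, np.clip(ls, np.log(self.sigma_floor), 12.0)

    def predict(self, cbct: ArrayLike) -> GeneratorOutput:
        """Deterministic forward pass (dropout off)."""
        self._check_fitted()
        vol = cbct if isinstance(cbct, Volume) else Volume(cbct, semantics="normalized")
        vol.require_semantics("normalized")
        sct, ls = self._forward_volume(_values(vol))
        return GeneratorOutput(
            sct=vol.like(sct, semantics="normalized"),
            log_scale=vol.like(ls, semantics="scale"),
        )

    def stochastic_predict(self, cbct: ArrayLike, dropout: float,
                           rng: np.random.Generator) -> GeneratorOutput:
        """One forward pass with inference-time dropout (for MC dropout)."""
        self._check_fitted()
        vol = cbct if isinstance(cbct, Volume) else Volume(cbct, semantics="normalized")
        sct, ls = self._forward_volume(_values(vol), dropout=dropout, rng=rng)
        return GeneratorOutput(
            sct=vol.like(sct, semantics="normalized"),
            log_scale=vol.like(ls, semantics="scale"),
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise RuntimeError("translator is not fitted; call fit() first")

    # -- persistence -------------------------------------------------------
    def save(self, directory: str | os.PathLike) -> None:
        """Checkpoint: one .npz of weights plus a JSON config sidecar."""
        self._check_fitted()
        directory = str(directory)
        os.makedirs(directory, exist_ok=True)
        np.savez(os.path.join(directory, "weights.npz"), **self.net_.state_dict())
        meta = {"params": self.get_params(), "loss_history": self.loss_history_}
        with open(os.path.join(directory, "config.json"), "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, directory: str | os.PathLike) -> "HeteroscedasticTranslator":
        directory = str(directory)
        with open(os.path.join(directory, "config.json")) as fh:
            meta = json.load(fh)
        est = cls(**meta["params"])
        est.net_ = UNet(in_ch=2, out_ch=2, width=est.width, nd=est._nd(),
                        depth=est.depth, seed=est.seed)
        with np.load(os.path.join(directory, "weights.npz")) as state:
            est.net_.load_state_dict(dict(state))
        est.loss_history_ = meta["loss_history"]
        est.n_epochs_ = len(est.loss_history_)
        return est


def train(cohort: Sequence[PairedSample], config: Optional[TrainConfig] = None
          ) -> HeteroscedasticTranslator:
    """Preprocess a phantom cohort and fit the translator (wrapper)."""
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    config = config or TrainConfig()
    X = [clip_and_normalize(s.cbct) for s in cohort]
    y = [clip_and_normalize(s.ct) for s in cohort]
    masks = None
    if config.loss_region == "external":
        masks = [s.structures["external"] for s in cohort]
    est = HeteroscedasticTranslator(**dataclasses.asdict(config))
    return est.fit(X, y, masks=masks)


def predict(model: HeteroscedasticTranslator, cbct: Volume) -> GeneratorOutput:
    """Deterministic inference on a normalized CBCT volume (wrapper)."""
    return model.predict(cbct)
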