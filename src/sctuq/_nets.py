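"""Minimal numpy CNN machinery: conv / pool / dropout layers, a compact
U-Net-style encoder-decoder with a two-channel head, a small patch
discriminator, and Adam.

Dimension-agnostic over 2 or 3 spatial axes. Tensors are ``(B, C, *spatial)``
in float32 working precision. Convolutions are 3^nd kernels with same-padding
evaluated as one batched GEMM over a shifted-slice im2col layout. Everything
is seeded and deterministic on one device.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

# float32 is the working precision; tests may switch to float64 for
# finite-difference gradient verification
DTYPE = np.float32


def _pad_spatial(x: np.ndarray, nd: int) -> np.ndarray:
    return np.pad(x, [(0, 0), (0, 0)] + [(1, 1)] * nd)


class Conv:
    """3^nd 'same' convolution with bias.

    Works in float32 via a shifted-slice im2col: the 3^nd translated copies of
    the padded input are stacked channel-first, so the whole convolution is
    one batched GEMM against a (cout, 3^nd * cin) weight matrix.
    """

    def __init__(self, cin: int, cout: int, nd: int, rng: np.random.Generator,
                 w_scale: Optional[float] = None, bias_init: float = 0.0):
        k = 3
        fan_in = cin * k ** nd
        scale = np.sqrt(2.0 / fan_in) if w_scale is None else w_scale
        self.W = rng.normal(0.0, scale, size=(cout, cin) + (k,) * nd).astype(DTYPE)
        self.b = np.full(cout, float(bias_init), dtype=DTYPE)
        self.nd = nd
        self.cin = cin
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: Optional[np.ndarray] = None
        self._spatial: Optional[tuple] = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _wmat(self) -> np.ndarray:
        # (O, C, *3) -> (O, *3, C) -> (O, 3^nd * C), matching the cols layout
        perm = (0,) + tuple(range(2, 2 + self.nd)) + (1,)
        return np.ascontiguousarray(self.W.transpose(perm)).reshape(self.W.shape[0], -1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        nd = self.nd
        S = x.shape[2:]
        xp = _pad_spatial(np.asarray(x, dtype=DTYPE), nd)
        blocks = []
        for k_idx in np.ndindex(*([3] * nd)):
            sl = (slice(None), slice(None)) + tuple(
                slice(i, i + S[d]) for d, i in enumerate(k_idx)
            )
            blocks.append(xp[sl])
        cols = np.concatenate(blocks, axis=1).reshape(x.shape[0], -1, int(np.prod(S)))
        self._cols = cols
        self._spatial = S
        out = np.matmul(self._wmat(), cols)  # (B, O, N)
        out = out.reshape((x.shape[0], self.W.shape[0]) + S)
        return out + self.b.reshape((1, -1) + (1,) * nd)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        nd = self.nd
        B = dy.shape[0]
        S = self._spatial
        cout = self.W.shape[0]
        dyf = np.asarray(dy, dtype=DTYPE).reshape(B, cout, -1)
        dWm = np.tensordot(dyf, self._cols, axes=([0, 2], [0, 2]))  # (O, 3^nd*C)
        perm_back = (0, 1 + nd) + tuple(range(1, 1 + nd))
        self.dW[...] = dWm.reshape((cout,) + (3,) * nd + (self.cin,)).transpose(perm_back)
        self.db[...] = dyf.sum(axis=(0, 2))
        dcols = np.matmul(self._wmat().T, dyf)  # (B, 3^nd*C, N)
        dcols = dcols.reshape((B, 3 ** nd, self.cin) + S)
        dxp = np.zeros((B, self.cin) + tuple(s + 2 for s in S), dtype=DTYPE)
        for k, k_idx in enumerate(np.ndindex(*([3] * nd))):
            dst = (slice(None), slice(None)) + tuple(
                slice(i, i + S[d]) for d, i in enumerate(k_idx)
            )
            dxp[dst] += dcols[:, k]
        inner = (slice(None), slice(None)) + (slice(1, -1),) * nd
        return dxp[inner]


def relu(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    y = np.maximum(x, 0.0)
    return y, x > 0


def relu_bwd(dy: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dy * mask


def avg_pool(x: np.ndarray, nd: int) -> np.ndarray:
    for ax in range(2, 2 + nd):
        s = list(x.shape)
        s[ax] //= 2
        s.insert(ax + 1, 2)
        x = x.reshape(s).mean(axis=ax + 1)
    return x


def avg_pool_bwd(dy: np.ndarray, nd: int) -> np.ndarray:
    for ax in range(2, 2 + nd):
        dy = np.repeat(dy, 2, axis=ax)
    return dy / (2 ** nd)


def upsample(x: np.ndarray, nd: int) -> np.ndarray:
    for ax in range(2, 2 + nd):
        x = np.repeat(x, 2, axis=ax)
    return x


def upsample_bwd(dy: np.ndarray, nd: int) -> np.ndarray:
    for ax in range(2, 2 + nd):
        s = list(dy.shape)
        s[ax] //= 2
        s.insert(ax + 1, 2)
        dy = dy.reshape(s).sum(axis=ax + 1)
    return dy


def dropout_mask(shape, rate: float, rng: Optional[np.random.Generator]) -> Optional[np.ndarray]:
    if rate <= 0.0 or rng is None:
        return None
    keep = 1.0 - rate
    return ((rng.random(shape) < keep) / keep).astype(DTYPE)


class UNet:
    """Configurable-depth U-Net encoder-decoder with a small-init head.

    ``depth`` pooling levels double the channel count per level (capped at
    ``4 * width``); each decoder block carries a dropout site after each of
    its two convolutions, which is where MC dropout is injected at inference.
    A deep enough decoder matters here: inferring a global shading/offset
    field at a voxel deep inside the body requires a receptive field that
    reaches the background.

    With ``residual=True`` (the default for image translation) the first
    output channel is predicted as a correction added to the first input
    channel; the second output channel is the log of the aleatoric scale and
    its head bias starts at ``log_sigma_bias`` (a generic tens-of-HU noise
    prior in normalised units) so the scale channel converges quickly.
    """

    def __init__(self, in_ch: int = 1, out_ch: int = 2, width: int = 16,
                 nd: int = 2, depth: int = 2, seed: int = 0,
                 residual: bool = True, log_sigma_bias: float = -3.5):
        rng = np.random.default_rng(seed)
        c = int(width)
        self.nd = nd
        self.depth = int(depth)
        self.residual = residual
        self.out_ch = out_ch
        ch = [min(c * 2 ** l, 4 * c) for l in range(self.depth + 1)]
        self.enc: List[Tuple[Conv, Conv]] = []
        prev = in_ch
        for l in range(self.depth):
            self.enc.append((Conv(prev, ch[l], nd, rng), Conv(ch[l], ch[l], nd, rng)))
            prev = ch[l]
        self.bottom = (Conv(prev, ch[-1], nd, rng), Conv(ch[-1], ch[-1], nd, rng))
        self.dec: List[Tuple[Conv, Conv]] = []
        prev = ch[-1]
        for l in reversed(range(self.depth)):
            self.dec.append((Conv(prev + ch[l], ch[l], nd, rng),
                             Conv(ch[l], ch[l], nd, rng)))
            prev = ch[l]
        self.head = Conv(prev, out_ch, nd, rng, w_scale=0.01)
        if out_ch >= 2:
            self.head.b[1] = log_sigma_bias
        self._c: dict = {}

    def layers(self) -> List[Conv]:
        out = []
        for a, b in self.enc:
            out += [a, b]
        out += list(self.bottom)
        for a, b in self.dec:
            out += [a, b]
        out.append(self.head)
        return out

    def forward(self, x: np.ndarray, dropout: float = 0.0,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        nd = self.nd
        if any(s % (2 ** self.depth) for s in x.shape[2:]):
            raise ValueError(
                f"spatial dims must be divisible by {2 ** self.depth}, got {x.shape[2:]}"
            )
        x = np.asarray(x, dtype=DTYPE)
        c = self._c = {"enc_masks": [], "dec_masks": [], "drops": [], "splits": []}
        h = x
        skips = []
        for ca, cb in self.enc:
            h, m1 = relu(ca.forward(h))
            h, m2 = relu(cb.forward(h))
            c["enc_masks"].append((m1, m2))
            skips.append(h)
            h = avg_pool(h, nd)
        h, mb1 = relu(self.bottom[0].forward(h))
        h, mb2 = relu(self.bottom[1].forward(h))
        c["bottom_masks"] = (mb1, mb2)
        for (ca, cb), skip in zip(self.dec, reversed(skips)):
            u = upsample(h, nd)
            c["splits"].append(u.shape[1])
            h = np.concatenate([u, skip], axis=1)
            h, m1 = relu(ca.forward(h))
            dm1 = dropout_mask(h.shape, dropout, rng)
            if dm1 is not None:
                h = h * dm1
            h, m2 = relu(cb.forward(h))
            dm2 = dropout_mask(h.shape, dropout, rng)
            if dm2 is not None:
                h = h * dm2
            c["dec_masks"].append((m1, m2))
            c["drops"].append((dm1, dm2))
        y = self.head.forward(h)
        if self.residual:
            y[:, 0:1] += x[:, 0:1]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        nd = self.nd
        c = self._c
        g = self.head.backward(dy)
        skip_grads = []
        for (ca, cb), (m1, m2), (dm1, dm2), split in zip(
            reversed(self.dec), reversed(c["dec_masks"]),
            reversed(c["drops"]), reversed(c["splits"])
        ):
            if dm2 is not None:
                g = g * dm2
            g = relu_bwd(g, m2)
            g = cb.backward(g)
            if dm1 is not None:
                g = g * dm1
            g = relu_bwd(g, m1)
            g = ca.backward(g)
            du, dskip = g[:, :split], g[:, split:]
            skip_grads.append(dskip)
            g = upsample_bwd(du, nd)
        mb1, mb2 = c["bottom_masks"]
        g = relu_bwd(g, mb2)
        g = self.bottom[1].backward(g)
        g = relu_bwd(g, mb1)
        g = self.bottom[0].backward(g)
        # skip_grads were collected topmost-first; the encoder unwinds deepest-first
        for (ca, cb), (m1, m2), dskip in zip(
            reversed(self.enc), reversed(c["enc_masks"]), reversed(skip_grads)
        ):
            g = avg_pool_bwd(g, nd)
            g = g + dskip
            g = relu_bwd(g, m2)
            g = cb.backward(g)
            g = relu_bwd(g, m1)
            g = ca.backward(g)
        if self.residual:
            g = g.copy()
            g[:, 0:1] += dy[:, 0:1]
        return g

    # -- (de)serialisation -------------------------------------------------
    def state_dict(self) -> dict:
        out = {}
        for i, layer in enumerate(self.layers()):
            out[f"W{i}"] = layer.W
            out[f"b{i}"] = layer.b
        return out

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers()):
            layer.W = np.asarray(state[f"W{i}"], dtype=np.float32)
            layer.b = np.asarray(state[f"b{i}"], dtype=np.float32)
            layer.dW = np.zeros_like(layer.W)
            layer.db = np.zeros_like(layer.b)


class PatchDiscriminator:
    """Tiny least-squares patch critic for the optional adversarial term."""

    def __init__(self, in_ch: int = 1, width: int = 8, nd: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.nd = nd
        self.c1 = Conv(in_ch, width, nd, rng)
        self.c2 = Conv(width, 2 * width, nd, rng)
        self.c3 = Conv(2 * width, 1, nd, rng)
        self._c: dict = {}

    def layers(self) -> List[Conv]:
        return [self.c1, self.c2, self.c3]

    def forward(self, x: np.ndarray) -> float:
        nd = self.nd
        c = self._c = {}
        h1, c["m1"] = relu(self.c1.forward(x))
        p1 = avg_pool(h1, nd)
        h2, c["m2"] = relu(self.c2.forward(p1))
        p2 = avg_pool(h2, nd)
        score = self.c3.forward(p2)
        c["shape"] = score.shape
        return float(score.mean())

    def backward(self, dscore: float) -> np.ndarray:
        nd = self.nd
        c = self._c
        g = np.full(c["shape"], dscore / np.prod(c["shape"]))
        g = self.c3.backward(g)
        g = avg_pool_bwd(g, nd)
        g = relu_bwd(g, c["m2"])
        g = self.c2.backward(g)
        g = avg_pool_bwd(g, nd)
        g = relu_bwd(g, c["m1"])
        return self.c1.backward(g)


class Adam:
    """Adam with optional global-norm gradient clipping."""

    def __init__(self, layers: List[Conv], lr: float = 2e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, grad_clip: float = 0.0):
        self.layers = layers
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.grad_clip = grad_clip
        self.t = 0
        self.m = [np.zeros_like(p) for layer in layers for p, _ in layer.params()]
        self.v = [np.zeros_like(p) for layer in layers for p, _ in layer.params()]

    def step(self) -> None:
        pairs = [pg for layer in self.layers for pg in layer.params()]
        if self.grad_clip > 0:
            norm = np.sqrt(sum(float(np.sum(g * g)) for _, g in pairs))
            if norm > self.grad_clip:
                scale = self.grad_clip / (norm + 1e-12)
                for _, g in pairs:
                    g *= scale
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, (p, g) in enumerate(pairs):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
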