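"""A 3D U-Net implemented directly on numpy arrays.

The segmentation stage needs a small encoder-decoder convolutional network
with leaky-ReLU activations, trainable with SGD on Dice + cross-entropy
loss.  This module implements the forward pass and the analytic backward
pass by hand on numpy arrays: 3x3x3 "same" convolutions are evaluated as 27
shift-and-accumulate channel matmuls (memory-light, BLAS-backed), pooling
is 2x2x2 max, upsampling is nearest-neighbour, and skip connections are
channel concatenations.  Everything is float32 and fully deterministic
given the initialisation seed, which makes train/predict runs
bit-reproducible on a fixed platform.

Layout convention: activations are (B, C, D, H, W); convolution weights are
(C_out, C_in, 3, 3, 3).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3d", "LeakyReLU", "UNet3D", "softmax_fg", "dice_ce_loss_and_grad", "SGD"]


class Conv3d:
    """3x3x3 (or 1x1x1) same-padding convolution with bias."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 negative_slope: float = 0.01):
        fan_in = c_in * kernel ** 3
        # He initialisation adjusted for the leaky-ReLU gain
        gain = np.sqrt(2.0 / (1.0 + negative_slope ** 2))
        std = gain / np.sqrt(fan_in)
        self.w = (rng.standard_normal((c_out, c_in, kernel, kernel, kernel)) * std).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kernel = kernel
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None

    @property
    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        B, C, D, H, W = x.shape
        if self.kernel == 1:
            if keep:
                self._xp = x
            out = np.einsum("oc,bcdhw->bodhw", self.w[:, :, 0, 0, 0], x, optimize=True)
            out += self.b.reshape(1, -1, 1, 1, 1)
            return out.astype(np.float32, copy=False)
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        if keep:
            self._xp = xp
        out = np.broadcast_to(
            self.b.reshape(1, -1, 1, 1, 1), (B, self.w.shape[0], D, H, W)
        ).astype(np.float32).copy()
        for dz in range(3):
            for dy in range(3):
                for dx in range(3):
                    v = xp[:, :, dz:dz + D, dy:dy + H, dx:dx + W]
                    out += np.einsum(
                        "oc,bcdhw->bodhw", self.w[:, :, dz, dy, dx], v, optimize=True
                    )
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        assert self._xp is not None, "forward(keep=True) must precede backward"
        B, Co, D, H, W = gout.shape
        self.gb[:] = gout.sum(axis=(0, 2, 3, 4))
        if self.kernel == 1:
            x = self._xp
            self.gw[:, :, 0, 0, 0] = np.einsum("bodhw,bcdhw->oc", gout, x, optimize=True)
            gx = np.einsum("oc,bodhw->bcdhw", self.w[:, :, 0, 0, 0], gout, optimize=True)
            self._xp = None
            return gx.astype(np.float32, copy=False)
        xp = self._xp
        gxp = np.zeros_like(xp)
        for dz in range(3):
            for dy in range(3):
                for dx in range(3):
                    v = xp[:, :, dz:dz + D, dy:dy + H, dx:dx + W]
                    self.gw[:, :, dz, dy, dx] = np.einsum(
                        "bodhw,bcdhw->oc", gout, v, optimize=True
                    )
                    gxp[:, :, dz:dz + D, dy:dy + H, dx:dx + W] += np.einsum(
                        "oc,bodhw->bcdhw", self.w[:, :, dz, dy, dx], gout, optimize=True
                    )
        self._xp = None
        return gxp[:, :, 1:-1, 1:-1, 1:-1]


class LeakyReLU:
    def __init__(self, negative_slope: float = 0.01):
        self.slope = np.float32(negative_slope)
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        mask = x >= 0
        if keep:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = np.where(self._mask, gout, self.slope * gout)
        self._mask = None
        return g


def _maxpool(x: np.ndarray):
    B, C, D, H, W = x.shape
    r = x.reshape(B, C, D // 2, 2, H // 2, 2, W // 2, 2)
    out = r.max(axis=(3, 5, 7))
    return out, r, out

def _maxpool_backward(gout: np.ndarray, r: np.ndarray, out: np.ndarray) -> np.ndarray:
    B, C, D2, H2, W2 = gout.shape
    o = out.reshape(B, C, D2, 1, H2, 1, W2, 1)
    mask = (r == o)
    counts = mask.sum(axis=(3, 5, 7), keepdims=True)
    g = mask * (gout.reshape(B, C, D2, 1, H2, 1, W2, 1) / counts)
    return g.reshape(B, C, D2 * 2, H2 * 2, W2 * 2)


def _upsample(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

def _upsample_backward(gout: np.ndarray) -> np.ndarray:
    B, C, D, H, W = gout.shape
    return gout.reshape(B, C, D // 2, 2, H // 2, 2, W // 2, 2).sum(axis=(3, 5, 7))


class UNet3D:
    """Encoder-decoder network with skip connections for 2-class voxel scores.

    ``levels`` resolution levels (``levels - 1`` poolings); channel width
    doubles per level from ``base_channels``, capped at ``max_channels``.
    Each level runs two 3x3x3 convolutions with leaky-ReLU; the head is a
    1x1x1 convolution to 2 class channels (logits).
    """

    def __init__(self, levels: int, base_channels: int, seed: int,
                 max_channels: int = 320, negative_slope: float = 0.01,
                 in_channels: int = 1, n_classes: int = 2):
        if levels < 2:
            raise ValueError("need at least 2 resolution levels")
        rng = np.random.default_rng(seed)
        self.levels = levels
        self.negative_slope = negative_slope
        ch = [min(base_channels * 2 ** i, max_channels) for i in range(levels)]
        self.channels = ch

        def block(cin, cout):
            return [
                Conv3d(cin, cout, 3, rng, negative_slope), LeakyReLU(negative_slope),
                Conv3d(cout, cout, 3, rng, negative_slope), LeakyReLU(negative_slope),
            ]

        self.enc = []
        cin = in_channels
        for i in range(levels):
            self.enc.append(block(cin, ch[i]))
            cin = ch[i]
        self.dec = []
        for i in reversed(range(levels - 1)):
            self.dec.append(block(ch[i + 1] + ch[i], ch[i]))
        self.head = Conv3d(ch[0], n_classes, 1, rng, negative_slope)

    # -- parameter plumbing -------------------------------------------------

    def parameters(self):
        layers = [l for blk in self.enc + self.dec for l in blk if isinstance(l, Conv3d)]
        layers.append(self.head)
        out = []
        for l in layers:
            out.extend(l.params)
        return out

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state length mismatch")
        for (p, _), s in zip(params, state):
            p[...] = s

    def required_divisor(self) -> int:
        return 2 ** (self.levels - 1)

    # -- forward / backward -------------------------------------------------

    def _check_shape(self, x: np.ndarray) -> None:
        div = self.required_divisor()
        if any(d % div for d in x.shape[2:]):
            raise ValueError(
                f"spatial shape {x.shape[2:]} must be divisible by {div} "
                f"for {self.levels} resolution levels"
            )

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None, None]
        elif x.ndim == 4:
            x = x[:, None]
        self._check_shape(x)
        skips = []
        pools = []
        h = x
        for i, blk in enumerate(self.enc):
            for layer in blk:
                h = layer.forward(h, keep=keep)
            if i < self.levels - 1:
                skips.append(h)
                h, r, o = _maxpool(h)
                pools.append((r, o))
        concat_splits = []
        for j, blk in enumerate(self.dec):
            h = _upsample(h)
            skip = skips[-(j + 1)]
            concat_splits.append(h.shape[1])
            h = np.concatenate([h, skip], axis=1)
            for layer in blk:
                h = layer.forward(h, keep=keep)
        logits = self.head.forward(h, keep=keep)
        if keep:
            self._cache = (pools, concat_splits)
        return logits

    def backward(self, glogits: np.ndarray) -> None:
        pools, concat_splits = self._cache
        g = self.head.backward(glogits)
        gskips = [None] * (self.levels - 1)
        for j in reversed(range(len(self.dec))):
            for layer in reversed(self.dec[j]):
                g = layer.backward(g)
            split = concat_splits[j]
            g_up, g_skip = g[:, :split], g[:, split:]
            gskips[self.levels - 2 - j] = g_skip
            g = _upsample_backward(g_up)
        for i in reversed(range(self.levels)):
            if i < self.levels - 1:
                r, o = pools[i]
                g = _maxpool_backward(g, r, o)
                g = g + gskips[i]
            for layer in reversed(self.enc[i]):
                g = layer.backward(g)
        self._cache = None


def softmax_fg(logits: np.ndarray) -> np.ndarray:
    """Foreground probability from 2-channel logits (numerically stable)."""
    from scipy.special import expit

    d = logits[:, 1] - logits[:, 0]
    return expit(d)


def dice_ce_loss_and_grad(logits: np.ndarray, target: np.ndarray,
                          eps: float = 1e-6) -> tuple[float, float, float, np.ndarray]:
    """Mean of soft-Dice loss and voxelwise cross-entropy, with logit gradient.

    ``target`` is a binary (B, D, H, W) array.  Returns
    (total, dice_loss, ce_loss, grad wrt logits).  The soft-Dice term is
    computed globally over the batch on the foreground probability.
    """
    target = np.asarray(target)
    y = target.astype(np.float32)
    p1 = softmax_fg(logits).astype(np.float64)
    n = y.size

    # cross-entropy via log-sigmoid of the logit difference:
    # -log p1 = log(1 + e^-d), -log p0 = log(1 + e^d)
    d = (logits[:, 1] - logits[:, 0]).astype(np.float64)
    ce = float(np.where(target > 0, np.logaddexp(0.0, -d), np.logaddexp(0.0, d)).mean())

    s_p = p1.sum()
    s_y = float(y.sum())
    s_py = float((p1 * y).sum())
    dice = (2.0 * s_py + eps) / (s_p + s_y + eps)
    dice_loss = 1.0 - dice

    # gradients wrt the logit difference d, then split to the two channels
    g_ce = (p1 - y) / n
    denom = (s_p + s_y + eps)
    g_dice_p = -(2.0 * y * denom - (2.0 * s_py + eps)) / (denom * denom)
    g_d = 0.5 * (g_ce + g_dice_p * p1 * (1.0 - p1))
    glogits = np.empty_like(logits)
    glogits[:, 1] = g_d.astype(np.float32)
    glogits[:, 0] = (-g_d).astype(np.float32)
    total = 0.5 * (ce + dice_loss)
    return total, dice_loss, ce, glogits


class SGD:
    """Stochastic gradient descent with classical momentum.

    ``clip_norm`` rescales the global gradient norm when it exceeds the
    bound, which keeps heavy-momentum runs stable in float32.
    """

    def __init__(self, params, lr: float, momentum: float = 0.0,
                 clip_norm: float | None = 10.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.clip_norm = clip_norm
        self.velocity = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        scale = 1.0
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for _, g in self.params))
            if total > self.clip_norm:
                scale = self.clip_norm / total
        for (p, g), v in zip(self.params, self.velocity):
            if self.momentum:
                v *= self.momentum
                v -= (self.lr * scale) * g
                p += v
            else:
                p -= (self.lr * scale) * g

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0
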