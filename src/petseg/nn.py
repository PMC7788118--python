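"""Minimal numpy neural-network engine for the 3D U-Net.

Implements exactly the layers the segmentation network needs — 3D "same"
convolution, ReLU, 2x max-pooling, nearest-neighbour 2x up-sampling, batch
normalization, dropout, sigmoid — with hand-written backpropagation and an
Adam optimizer.  Data layout is channels-last ``(batch, z, y, x, channels)``
in float32; convolutions are evaluated as a sum of shifted-slice GEMMs,
which keeps the inner loops inside BLAS.

Everything is seeded: weight initialization, mini-batch shuffling and
dropout all draw from generators derived from a single integer seed, so a
single-threaded run is bit-reproducible.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import expit

__all__ = ["Conv3d", "BatchNorm", "Adam", "UNet3D"]


class Conv3d:
    """3D convolution with odd kernel, stride 1, zero "same" padding."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.cin, self.cout, self.k = cin, cout, k
        std = np.sqrt(2.0 / (k ** 3 * cin))  # He initialization
        self.W = rng.normal(0.0, std, (k ** 3, cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._offsets = list(itertools.product(range(k), repeat=3))

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        B, D, H, W_, C = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
        self._xp, self._shape = xp, (B, D, H, W_)
        out = np.broadcast_to(self.b, (B * D * H * W_, self.cout)).copy()
        for i, (dz, dy, dx) in enumerate(self._offsets):
            xs = xp[:, dz:dz + D, dy:dy + H, dx:dx + W_, :].reshape(-1, self.cin)
            out += xs @ self.W[i]
        return out.reshape(B, D, H, W_, self.cout)

    def backward(self, g: np.ndarray) -> np.ndarray:
        p = self.k // 2
        B, D, H, W_ = self._shape
        gf = np.ascontiguousarray(g).reshape(-1, self.cout)
        self.gb[:] = gf.sum(axis=0)
        gxp = np.zeros_like(self._xp)
        for i, (dz, dy, dx) in enumerate(self._offsets):
            xs = self._xp[:, dz:dz + D, dy:dy + H, dx:dx + W_, :].reshape(-1, self.cin)
            self.gW[i] = xs.T @ gf
            gxp[:, dz:dz + D, dy:dy + H, dx:dx + W_, :] += \
                (gf @ self.W[i].T).reshape(B, D, H, W_, self.cin)
        self._xp = None
        return gxp[:, p:-p, p:-p, p:-p, :] if p else gxp


class BatchNorm:
    """Per-channel batch normalization over batch + spatial axes."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.ggamma = np.zeros(c, dtype=np.float32)
        self.gbeta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 1, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._xhat, self._inv, self._n = xhat, inv, x[..., 0].size
        return (self.gamma * xhat + self.beta).astype(np.float32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        axes = (0, 1, 2, 3)
        xhat, inv, n = self._xhat, self._inv, self._n
        self.ggamma[:] = (g * xhat).sum(axis=axes)
        self.gbeta[:] = g.sum(axis=axes)
        gx = (self.gamma * inv / n) * (
            n * g - g.sum(axis=axes) - xhat * (g * xhat).sum(axis=axes)
        )
        self._xhat = None
        return gx.astype(np.float32)


def _relu_fwd(x):
    mask = x > 0
    return x * mask, mask


def _maxpool_fwd(x):
    B, D, H, W_, C = x.shape
    xr = x.reshape(B, D // 2, 2, H // 2, 2, W_ // 2, 2, C)
    m = xr.max(axis=(2, 4, 6))
    mask = xr == m[:, :, None, :, None, :, None, :]
    counts = mask.sum(axis=(2, 4, 6))
    return m, (mask, counts, x.shape)


def _maxpool_bwd(g, cache):
    mask, counts, shape = cache
    gb = (g / counts)[:, :, None, :, None, :, None, :]
    return (mask * gb).reshape(shape).astype(np.float32)


def _upsample_fwd(x):
    return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)


def _upsample_bwd(g):
    B, D, H, W_, C = g.shape
    return g.reshape(B, D // 2, 2, H // 2, 2, W_ // 2, 2, C).sum(axis=(2, 4, 6))


class Adam:
    """Adam optimizer over (param, grad) array pairs, updated in place."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class _Block:
    """Two convolutions, each followed by ReLU."""

    def __init__(self, cin, cmid, k, rng):
        self.c1 = Conv3d(cin, cmid, k, rng)
        self.c2 = Conv3d(cmid, cmid, k, rng)

    def params(self):
        return self.c1.params() + self.c2.params()

    def forward(self, x):
        h, self._m1 = _relu_fwd(self.c1.forward(x))
        out, self._m2 = _relu_fwd(self.c2.forward(h))
        return out

    def backward(self, g):
        g = self.c2.backward(g * self._m2)
        return self.c1.backward(g * self._m1)


class UNet3D:
    """Encoder-decoder segmentation network with skip connections.

    Encoder: per level a conv block (two kernel-``k`` convolutions + ReLU),
    2x max-pool, batch norm, dropout; features double per level.  A conv
    block forms the bottleneck.  Decoder: nearest up-sampling, concatenation
    with the same-level encoder output, conv block, batch norm, dropout.
    A final 1x1x1 convolution with sigmoid yields per-voxel probabilities.
    """

    def __init__(self, levels=3, features=8, kernel=5, dropout=0.2,
                 growth=2, seed=0):
        if levels < 1 or features < 1:
            raise ValueError("levels and features must be >= 1")
        rng = np.random.default_rng(seed)
        self.levels, self.dropout = levels, dropout
        f = [features * growth ** l for l in range(levels + 1)]
        self.enc = []
        cin = 1
        for l in range(levels):
            self.enc.append({"block": _Block(cin, f[l], kernel, rng),
                             "bn": BatchNorm(f[l])})
            cin = f[l]
        self.bottleneck = _Block(cin, f[levels], kernel, rng)
        self.dec = []
        cin = f[levels]
        for l in reversed(range(levels)):
            self.dec.append({"block": _Block(cin + f[l], f[l], kernel, rng),
                             "bn": BatchNorm(f[l]), "level": l})
            cin = f[l]
        self.final = Conv3d(cin, 1, 1, rng)

    def params(self):
        out = []
        for e in self.enc:
            out += e["block"].params() + e["bn"].params()
        out += self.bottleneck.params()
        for d in self.dec:
            out += d["block"].params() + d["bn"].params()
        out += self.final.params()
        return out

    def _dropout_fwd(self, x, train, rng):
        if not train or self.dropout <= 0:
            return x, None
        keep = (rng.random(x.shape) >= self.dropout).astype(np.float32)
        keep /= (1.0 - self.dropout)
        return x * keep, keep

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        d = x.shape[1:4]
        if any(s % 2 ** self.levels for s in d):
            raise ValueError(
                f"input spatial shape {d} not divisible by 2^levels = {2 ** self.levels}")
        if train and rng is None:
            rng = np.random.default_rng(0)
        x = x.astype(np.float32)
        self._caches = []
        skips = []
        for e in self.enc:
            s = e["block"].forward(x)
            skips.append(s)
            pooled, pc = _maxpool_fwd(s)
            bn = e["bn"].forward(pooled, train)
            x, dmask = self._dropout_fwd(bn, train, rng)
            self._caches.append({"pool": pc, "drop": dmask})
        x = self.bottleneck.forward(x)
        self._dec_caches = []
        for d_ in self.dec:
            up = _upsample_fwd(x)
            skip = skips[d_["level"]]
            cat = np.concatenate([up, skip], axis=-1)
            h = d_["block"].forward(cat)
            bn = d_["bn"].forward(h, train)
            x, dmask = self._dropout_fwd(bn, train, rng)
            self._dec_caches.append({"split": up.shape[-1], "drop": dmask})
        z = self.final.forward(x)
        self._y = expit(z)
        return self._y

    def backward(self, gy: np.ndarray) -> None:
        """Backpropagate gradient of the loss w.r.t. the output probabilities."""
        g = gy * self._y * (1.0 - self._y)
        g = self.final.backward(g.astype(np.float32))
        skip_grads = {}
        for d_, c in zip(reversed(self.dec), reversed(self._dec_caches)):
            if c["drop"] is not None:
                g = g * c["drop"]
            g = d_["bn"].backward(g)
            g = d_["block"].backward(g)
            split = c["split"]
            gup, gskip = g[..., :split], g[..., split:]
            skip_grads[d_["level"]] = gskip
            g = _upsample_bwd(gup)
        g = self.bottleneck.backward(g)
        for l, (e, c) in reversed(list(enumerate(zip(self.enc, self._caches)))):
            if c["drop"] is not None:
                g = g * c["drop"]
            g = e["bn"].backward(g)
            g = _maxpool_bwd(g, c["pool"])
            g = g + skip_grads[l]
            g = e["block"].backward(g)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode forward pass (running BN stats, no dropout)."""
        return self.forward(x, train=False)

    # -- persistence ------------------------------------------------------
    def state_arrays(self) -> dict:
        arrs = {}
        for i, (p, _) in enumerate(self.params()):
            arrs[f"p{i}"] = p
        for i, e in enumerate(self.enc):
            arrs[f"enc{i}_rm"] = e["bn"].running_mean
            arrs[f"enc{i}_rv"] = e["bn"].running_var
        for i, d_ in enumerate(self.dec):
            arrs[f"dec{i}_rm"] = d_["bn"].running_mean
            arrs[f"dec{i}_rv"] = d_["bn"].running_var
        return arrs

    def load_state_arrays(self, arrs: dict) -> None:
        for i, (p, _) in enumerate(self.params()):
            p[...] = arrs[f"p{i}"]
        for i, e in enumerate(self.enc):
            e["bn"].running_mean = np.asarray(arrs[f"enc{i}_rm"])
            e["bn"].running_var = np.asarray(arrs[f"enc{i}_rv"])
        for i, d_ in enumerate(self.dec):
            d_["bn"].running_mean = np.asarray(arrs[f"dec{i}_rm"])
            d_["bn"].running_var = np.asarray(arrs[f"dec{i}_rv"])
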