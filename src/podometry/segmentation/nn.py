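"""A compact CPU encoder-decoder conv-net, in pure numpy.

Implements exactly what the segmentation task needs: 3x3 "same"
convolutions via im2col, ReLU, 2x2 max-pooling, nearest-neighbor
upsampling, channel concatenation (skip connections), a sigmoid output
and a per-pixel weighted cross-entropy loss, with hand-written backward
passes and an Adam optimizer.  The architecture is a three-level
encoder-decoder with skip connections; input and output spatial shapes
are equal and the network is fully convolutional, so it can be applied
to any frame whose sides are multiples of four.
"""

from __future__ import annotations

import numpy as np

__all__ = ["EncoderDecoder", "Adam", "weighted_bce_with_logits"]


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) patches for 'same' convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, C, k, k, H, W)
    win = win.transpose(0, 1, 4, 5, 2, 3)
    return np.ascontiguousarray(win).reshape(n, c * k * k, h * w)


def _col2im(dcols: np.ndarray, shape, k: int, pad: int) -> np.ndarray:
    """Scatter-add the gradient of im2col back to the input layout."""
    n, c, h, w = shape
    d = dcols.reshape(n, c, k, k, h, w)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp


class _Conv:
    """k x k 'same' convolution with bias; He-initialized."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.k = k
        self.pad = k // 2

    def forward(self, x):
        self._shape = x.shape
        self._cols = _im2col(x, self.k, self.pad)
        n, _, hw = self._cols.shape
        f = self.w.shape[0]
        y = self.w.reshape(f, -1) @ self._cols + self.b[:, None]
        h, w = self._shape[2:]
        return y.reshape(n, f, h, w)

    def backward(self, dy):
        n, f, h, w = dy.shape
        dyf = dy.reshape(n, f, h * w)
        self.dw = np.einsum("nfp,ncp->fc", dyf, self._cols).reshape(self.w.shape)
        self.db = dyf.sum(axis=(0, 2))
        dcols = np.einsum("fc,nfp->ncp", self.w.reshape(f, -1), dyf)
        return _col2im(dcols, self._shape, self.k, self.pad)

    def params(self):
        return [(self.w, "dw", self), (self.b, "db", self)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _Pool2:
    """2x2 max pooling (requires even sides)."""

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        self._mask = xr == y[:, :, :, None, :, None]
        # break ties so gradient mass is conserved
        self._mask = self._mask / self._mask.sum(axis=(3, 5), keepdims=True)
        self._shape = x.shape
        return y

    def backward(self, dy):
        n, c, h, w = self._shape
        d = self._mask * dy[:, :, :, None, :, None]
        return d.reshape(n, c, h, w)


class _Up2:
    """Nearest-neighbor 2x upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class _Block:
    """conv-relu-conv-relu."""

    def __init__(self, c_in, c_out, rng):
        self.c1 = _Conv(c_in, c_out, 3, rng)
        self.r1 = _ReLU()
        self.c2 = _Conv(c_out, c_out, 3, rng)
        self.r2 = _ReLU()

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, dy):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(dy))))

    def params(self):
        return self.c1.params() + self.c2.params()


class EncoderDecoder:
    """Three-level encoder-decoder with skip connections, one logit map.

    Parameters
    ----------
    base_channels : width of the first level; deeper levels double it.
    in_channels : input image channels.
    seed : parameter initialization seed.
    """

    def __init__(self, base_channels: int = 8, in_channels: int = 1, seed: int = 0):
        rng = np.random.default_rng(seed)
        c = base_channels
        self.base_channels = c
        self.in_channels = in_channels
        self.enc1 = _Block(in_channels, c, rng)
        self.pool1 = _Pool2()
        self.enc2 = _Block(c, 2 * c, rng)
        self.pool2 = _Pool2()
        self.bott = _Block(2 * c, 4 * c, rng)
        self.up2 = _Up2()
        self.dec2 = _Block(4 * c + 2 * c, 2 * c, rng)
        self.up1 = _Up2()
        self.dec1 = _Block(2 * c + c, c, rng)
        self.head = _Conv(c, 1, 1, rng)

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits for input (N, C, H, W); H and W must be multiples of 4."""
        if x.ndim != 4 or x.shape[2] % 4 or x.shape[3] % 4:
            raise ValueError("input must be (N, C, H, W) with H, W multiples of 4")
        s1 = self.enc1.forward(x)
        s2 = self.enc2.forward(self.pool1.forward(s1))
        b = self.bott.forward(self.pool2.forward(s2))
        u2 = self.up2.forward(b)
        self._split2 = u2.shape[1]
        d2 = self.dec2.forward(np.concatenate([u2, s2], axis=1))
        u1 = self.up1.forward(d2)
        self._split1 = u1.shape[1]
        d1 = self.dec1.forward(np.concatenate([u1, s1], axis=1))
        return self.head.forward(d1)

    def backward(self, dlogits: np.ndarray) -> None:
        dd1 = self.head.backward(dlogits)
        dcat1 = self.dec1.backward(dd1)
        du1, ds1_skip = dcat1[:, : self._split1], dcat1[:, self._split1 :]
        dd2 = self.up1.backward(du1)
        dcat2 = self.dec2.backward(dd2)
        du2, ds2_skip = dcat2[:, : self._split2], dcat2[:, self._split2 :]
        db = self.up2.backward(du2)
        ds2 = self.pool2.backward(self.bott.backward(db)) + ds2_skip
        ds1 = self.pool1.backward(self.enc2.backward(ds2)) + ds1_skip
        self.enc1.backward(ds1)

    def params(self):
        blocks = [self.enc1, self.enc2, self.bott, self.dec2, self.dec1]
        out = []
        for blk in blocks:
            out += blk.params()
        out += self.head.params()
        return out

    # -- inference ---------------------------------------------------------
    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Per-pixel foreground probability for a single 2D image.

        Frames whose sides are not multiples of four are reflect-padded
        and the output cropped back.
        """
        img = np.asarray(image, dtype=np.float64)
        if img.ndim != 2:
            raise ValueError("expected a single 2D image")
        h, w = img.shape
        ph = (-h) % 4
        pw = (-w) % 4
        x = np.pad(img, ((0, ph), (0, pw)), mode="reflect")[None, None]
        logits = self.forward(x)[0, 0, :h, :w]
        return 1.0 / (1.0 + np.exp(-logits))

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p for i, (p, _, _) in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, (p, _, _) in enumerate(self.params()):
            arr = np.asarray(state[f"p{i}"])
            if arr.shape != p.shape:
                raise ValueError("checkpoint does not match architecture")
            p[...] = arr


class Adam:
    """Adam optimizer over the network's parameter list."""

    def __init__(self, net: EncoderDecoder, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _, _ in net.params()]
        self.v = [np.zeros_like(p) for p, _, _ in net.params()]

    def step(self) -> None:
        self.t += 1
        for i, (p, gname, owner) in enumerate(self.net.params()):
            g = getattr(owner, gname)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def weighted_bce_with_logits(logits: np.ndarray, targets: np.ndarray,
                             weights: np.ndarray):
    """Per-pixel weighted binary cross-entropy.

    Returns ``(loss, dlogits)`` where the loss is the weight-normalized
    mean of w·(softplus(z) − y·z) and ``dlogits`` its gradient.
    """
    z, y, w = logits, targets, weights
    sp = np.logaddexp(0.0, z)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("weights sum to zero")
    loss = float((w * (sp - y * z)).sum() / wsum)
    sig = 1.0 / (1.0 + np.exp(-z))
    dlogits = w * (sig - y) / wsum
    return loss, dlogits
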