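"""A small self-contained 3D convolutional network toolkit.

Implements exactly what the block denoiser needs — 3D convolutions
(im2col + GEMM) with hand-derived backward passes, ReLU, nearest-neighbor
upsampling, a residual U-net, l1 loss and Adam — in float32 numpy.  The
scope is deliberately narrow: dense 3D conv nets of the residual-U-net
shape, trained on CPU at modest block sizes.

Layers cache what their backward pass needs; ``zero_grad`` clears parameter
gradients between steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Conv3d", "ResBlock", "ResUNet", "NetConfig", "Adam", "l1_loss", "build_network"]


class Conv3d:
    """3D convolution, kernel k^3, stride 1 or 2, 'same'-style padding k//2."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1, rng=None):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k**3
        # He initialization for ReLU networks
        self.W = (rng.standard_normal((c_out, c_in, k, k, k)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def n_params(self) -> int:
        return self.W.size + self.b.size

    def _im2col(self, x: np.ndarray):
        k, s = self.k, self.stride
        p = k // 2
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
        win = win[:, :, ::s, ::s, ::s]  # (N, ci, D', H', W', k, k, k)
        n, ci, d, h, w = win.shape[:5]
        cols = np.ascontiguousarray(win).reshape(n, ci, d * h * w, k**3)
        cols = cols.transpose(0, 1, 3, 2).reshape(n, ci * k**3, d * h * w)
        return cols, (d, h, w), x.shape[2:]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        cols, out_sp, pad_sp = self._im2col(x)
        Wm = self.W.reshape(self.c_out, -1)
        y = np.einsum("oc,ncp->nop", Wm, cols, optimize=True)
        y += self.b[None, :, None]
        self._cache = (cols, x.shape, pad_sp, out_sp)
        return y.reshape(x.shape[0], self.c_out, *out_sp)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, pad_sp, out_sp = self._cache
        n = x_shape[0]
        k, s = self.k, self.stride
        dyf = dy.reshape(n, self.c_out, -1).astype(np.float32)
        Wm = self.W.reshape(self.c_out, -1)
        self.dW += np.einsum("nop,ncp->oc", dyf, cols, optimize=True).reshape(self.W.shape)
        self.db += dyf.sum(axis=(0, 2))
        dcols = np.einsum("oc,nop->ncp", Wm, dyf, optimize=True)  # (N, ci*k^3, P)
        dcols = dcols.reshape(n, self.c_in, k, k, k, *out_sp)
        dxp = np.zeros((n, self.c_in) + tuple(pad_sp), dtype=np.float32)
        d, h, w = out_sp
        for a in range(k):
            for bb in range(k):
                for c in range(k):
                    dxp[
                        :,
                        :,
                        a : a + (d - 1) * s + 1 : s,
                        bb : bb + (h - 1) * s + 1 : s,
                        c : c + (w - 1) * s + 1 : s,
                    ] += dcols[:, :, a, bb, c]
        p = k // 2
        if p:
            dxp = dxp[:, :, p:-p, p:-p, p:-p]
        return dxp


class _ReLU:
    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, dy):
        return dy * self.mask


class _Upsample2:
    """Nearest-neighbor x2 upsampling; backward sums the 2x2x2 cells."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, dy):
        n, c, d, h, w = dy.shape
        return dy.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(3, 5, 7))


class ResBlock:
    """conv3-ReLU-conv3 with a kernel-1 dimension-matching skip; ReLU after the add."""

    def __init__(self, c_in: int, c_out: int, rng=None):
        self.conv1 = Conv3d(c_in, c_out, 3, rng=rng)
        self.conv2 = Conv3d(c_out, c_out, 3, rng=rng)
        self.skip = Conv3d(c_in, c_out, 1, rng=rng)
        self.r1 = _ReLU()
        self.r2 = _ReLU()

    def modules(self):
        return [self.conv1, self.conv2, self.skip]

    def forward(self, x):
        y = self.conv2.forward(self.r1.forward(self.conv1.forward(x)))
        return self.r2.forward(y + self.skip.forward(x))

    def backward(self, dy):
        dy = self.r2.backward(dy)
        dx = self.skip.backward(dy)
        dx += self.conv1.backward(self.r1.backward(self.conv2.backward(dy)))
        return dx


@dataclass(frozen=True)
class NetConfig:
    """Residual U-net layout: 3 encoder + 3 decoder residual blocks.

    ``widths`` are the per-level feature counts; ``in_channels`` equals
    2K (real/imaginary concatenated along the channel axis).  The
    full-scale profile (widths 160/224/384 with 10 channels) carries 23.8
    million trainable parameters; the desk-scale default is far smaller.
    """

    in_channels: int
    widths: tuple[int, int, int] = (160, 224, 384)
    seed: int = 0

    def __post_init__(self):
        if len(self.widths) != 3 or any(w <= 0 for w in self.widths):
            raise ValueError("widths must be three positive integers")
        if self.in_channels < 2 or self.in_channels % 2:
            raise ValueError("in_channels must be an even count (2K)")


class ResUNet:
    """3-level residual U-net with additive skip connections.

    Encoder: ResBlock, strided-conv downsample (x2) per level.  Decoder:
    nearest-neighbor upsample + conv, add the encoder skip, ResBlock; a
    final full-resolution ResBlock and a linear 3^3 projection head.
    Spatial input edges must be divisible by 4.
    """

    def __init__(self, cfg: NetConfig):
        self.cfg = cfg
        w1, w2, w3 = cfg.widths
        cio = cfg.in_channels
        rng = np.random.default_rng(cfg.seed)
        self.enc1 = ResBlock(cio, w1, rng)
        self.down1 = Conv3d(w1, w2, 3, stride=2, rng=rng)
        self.enc2 = ResBlock(w2, w2, rng)
        self.down2 = Conv3d(w2, w3, 3, stride=2, rng=rng)
        self.enc3 = ResBlock(w3, w3, rng)
        self.up1c = Conv3d(w3, w2, 3, rng=rng)
        self.dec1 = ResBlock(w2, w2, rng)
        self.up2c = Conv3d(w2, w1, 3, rng=rng)
        self.dec2 = ResBlock(w1, w1, rng)
        self.dec3 = ResBlock(w1, w1, rng)
        self.head = Conv3d(w1, cio, 3, rng=rng)
        self._relus = [_ReLU() for _ in range(4)]
        self._ups = [_Upsample2(), _Upsample2()]

    def modules(self):
        mods = []
        for blk in (self.enc1, self.enc2, self.enc3, self.dec1, self.dec2, self.dec3):
            mods.extend(blk.modules())
        mods.extend([self.down1, self.down2, self.up1c, self.up2c, self.head])
        return mods

    def params(self):
        out = []
        for m in self.modules():
            out.extend(m.params())
        return out

    def n_params(self) -> int:
        return sum(m.n_params() for m in self.modules())

    def zero_grad(self):
        for m in self.modules():
            m.dW[...] = 0
            m.db[...] = 0

    def forward(self, x: np.ndarray) -> np.ndarray:
        if any(s % 4 for s in x.shape[2:]):
            raise ValueError("spatial block edges must be divisible by 4")
        r = self._relus
        e1 = self.enc1.forward(x)
        e2 = self.enc2.forward(r[0].forward(self.down1.forward(e1)))
        e3 = self.enc3.forward(r[1].forward(self.down2.forward(e2)))
        u1 = r[2].forward(self.up1c.forward(self._ups[0].forward(e3)))
        d1 = self.dec1.forward(u1 + e2)
        u2 = r[3].forward(self.up2c.forward(self._ups[1].forward(d1)))
        d2 = self.dec2.forward(u2 + e1)
        return self.head.forward(self.dec3.forward(d2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        r = self._relus
        g = self.dec3.backward(self.head.backward(dy))
        g = self.dec2.backward(g)
        ge1 = g  # additive skip into enc1
        g = self._ups[1].backward(self.up2c.backward(r[3].backward(g)))
        g = self.dec1.backward(g)
        ge2 = g
        g = self._ups[0].backward(self.up1c.backward(r[2].backward(g)))
        g = self.enc3.backward(g)
        g = self.down2.backward(r[1].backward(g))
        g = self.enc2.backward(g + ge2)
        g = self.down1.backward(r[0].backward(g))
        return self.enc1.backward(g + ge1)

    # -- persistence ---------------------------------------------------
    def state_dict(self) -> dict:
        return {f"p{i}": p for i, (p, _) in enumerate(self.params())}

    def load_state_dict(self, state: dict):
        for i, (p, _) in enumerate(self.params()):
            p[...] = state[f"p{i}"]

    def save(self, path, extra: dict | None = None):
        meta = {
            "in_channels": self.cfg.in_channels,
            "widths": np.array(self.cfg.widths),
            "seed": self.cfg.seed,
        }
        if extra:
            meta.update(extra)
        np.savez(path, **self.state_dict(), **meta)

    @classmethod
    def load(cls, path) -> "ResUNet":
        with np.load(path) as z:
            cfg = NetConfig(
                in_channels=int(z["in_channels"]),
                widths=tuple(int(w) for w in z["widths"]),
                seed=int(z["seed"]),
            )
            net = cls(cfg)
            net.load_state_dict({k: z[k] for k in z.files if k.startswith("p")})
        return net


def build_network(cfg: NetConfig) -> tuple[ResUNet, int]:
    """Instantiate the residual U-net and report its trainable-parameter count."""
    net = ResUNet(cfg)
    return net, net.n_params()


def analytic_param_count(in_channels: int, widths: tuple[int, int, int]) -> int:
    """Closed-form layer-by-layer parameter sum (kernel volume * c_in * c_out + bias)."""

    def conv(ci, co, k):
        return k**3 * ci * co + co

    def res(ci, co):
        return conv(ci, co, 3) + conv(co, co, 3) + conv(ci, co, 1)

    w1, w2, w3 = widths
    cio = in_channels
    return (
        res(cio, w1)
        + conv(w1, w2, 3)
        + res(w2, w2)
        + conv(w2, w3, 3)
        + res(w3, w3)
        + conv(w3, w2, 3)
        + res(w2, w2)
        + conv(w2, w1, 3)
        + res(w1, w1)
        + res(w1, w1)
        + conv(w1, cio, 3)
    )


def l1_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its (sub)gradient w.r.t. ``pred``."""
    diff = pred - target
    return float(np.mean(np.abs(diff))), (np.sign(diff) / diff.size).astype(np.float32)


class Adam:
    """Adam over a network's (param, grad) pairs."""

    def __init__(self, net: ResUNet, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in net.params()]
        self.v = [np.zeros_like(p) for p, _ in net.params()]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for (p, g), m, v in zip(self.net.params(), self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
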