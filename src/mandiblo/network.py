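"""Minimal CPU convolutional network engine for heatmap regression.

Implements exactly the pieces the landmark localizer needs — 2-D
convolution, ReLU, 2x average pooling, nearest-neighbor upsampling,
residual blocks, and the recursive hourglass encoder–decoder — as plain
numpy arrays with hand-written backward passes and an Adam optimizer.
All computation is float64 and fully deterministic given a seeded
``numpy.random.Generator`` for initialization.

Layout convention: activations are (batch, channels, height, width).
All arrays are float32 for speed; the localizer's decode path converts
back to float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Conv2d:
    """Same-padded, stride-1 convolution (im2col + GEMM)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = rng.normal(0.0, std, size=(cin * k * k, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.cin, self.cout, self.k = cin, cout, k
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols_cache = None
        self._x_shape = None

    def _cols(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        p = self.k // 2
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(x, (self.k, self.k), axis=(2, 3))
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, C * self.k**2)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        B, C, H, W = x.shape
        cols = np.ascontiguousarray(self._cols(x))
        self._cols_cache = cols
        y = cols @ self.w + self.b
        return y.reshape(B, H, W, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, H, W = self._x_shape
        k, p = self.k, self.k // 2
        dy = np.ascontiguousarray(
            dout.transpose(0, 2, 3, 1), dtype=np.float32
        ).reshape(B * H * W, self.cout)
        self.dw += self._cols_cache.T @ dy
        self.db += dy.sum(axis=0)
        dcols = (dy @ self.w.T).reshape(B, H, W, C, k, k)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + H, j:j + W] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + H, p:p + W] if p else dxp

    def zero_grad(self):
        self.dw[...] = 0.0
        self.db[...] = 0.0


class ReLU:
    def forward(self, x):
        self._m = x > 0
        return x * self._m

    def backward(self, dout):
        return dout * self._m


class AvgPool2:
    def forward(self, x):
        B, C, H, W = x.shape
        self._shape = x.shape
        return x.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(self, dout):
        return np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0


class Upsample2:
    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout):
        B, C, H, W = dout.shape
        return dout.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class ResBlock:
    """conv3-relu-conv3 with an identity (or 1x1) skip, ReLU on the sum."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.c1 = Conv2d(cin, cout, 3, rng)
        self.r1 = ReLU()
        self.c2 = Conv2d(cout, cout, 3, rng)
        self.skip = Conv2d(cin, cout, 1, rng) if cin != cout else None
        self.r2 = ReLU()

    def forward(self, x):
        main = self.c2.forward(self.r1.forward(self.c1.forward(x)))
        s = self.skip.forward(x) if self.skip else x
        return self.r2.forward(main + s)

    def backward(self, dout):
        d = self.r2.backward(dout)
        dx = self.skip.backward(d) if self.skip else d
        dx = dx + self.c1.backward(self.r1.backward(self.c2.backward(d)))
        return dx

    def convs(self):
        yield self.c1
        yield self.c2
        if self.skip:
            yield self.skip


class Hourglass:
    """Recursive downsampling–upsampling module with residual skips."""

    def __init__(self, depth: int, ch: int, rng: np.random.Generator):
        self.up1 = ResBlock(ch, ch, rng)
        self.pool = AvgPool2()
        self.low1 = ResBlock(ch, ch, rng)
        self.inner = (
            Hourglass(depth - 1, ch, rng) if depth > 1 else ResBlock(ch, ch, rng)
        )
        self.low3 = ResBlock(ch, ch, rng)
        self.up = Upsample2()

    def forward(self, x):
        a = self.up1.forward(x)
        b = self.up.forward(
            self.low3.forward(
                self.inner.forward(self.low1.forward(self.pool.forward(x)))
            )
        )
        return a + b

    def backward(self, dout):
        dx = self.up1.backward(dout)
        d = self.pool.backward(
            self.low1.backward(
                self.inner.backward(
                    self.low3.backward(self.up.backward(dout))
                )
            )
        )
        return dx + d

    def convs(self):
        yield from self.up1.convs()
        yield from self.low1.convs()
        yield from self.inner.convs()
        yield from self.low3.convs()


class StackedHourglassNet:
    """Stacked hourglass network with intermediate supervision.

    Maps a single-channel image to ``stacks`` stacks of ``n_out``-channel
    heatmaps at the input resolution. Each stack refines the previous
    stack's belief maps through feature and prediction remapping.
    """

    def __init__(
        self,
        depth: int = 4,
        channels: int = 64,
        stacks: int = 2,
        n_out: int = 97,
        head_channels: int | None = None,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.depth, self.channels = depth, channels
        self.stacks, self.n_out = stacks, n_out
        # the 1x1 prediction from c features caps the output stack's rank
        # at c+1; the widening head + ReLU lifts it so many distinct
        # peaked maps can coexist
        self.head_channels = head_channels or max(channels, n_out)
        self.stem_conv = Conv2d(1, channels, 3, rng)
        self.stem_relu = ReLU()
        self.stem_res = ResBlock(channels, channels, rng)
        self.hgs, self.posts, self.preds = [], [], []
        self.heads, self.head_relus = [], []
        self.merge_feat, self.merge_pred = [], []
        for s in range(stacks):
            self.hgs.append(Hourglass(depth, channels, rng))
            self.posts.append(ResBlock(channels, channels, rng))
            self.heads.append(Conv2d(channels, self.head_channels, 1, rng))
            self.head_relus.append(ReLU())
            pred = Conv2d(self.head_channels, n_out, 1, rng)
            # zero-init the prediction layer: the net starts from the
            # benign all-zero output instead of the huge random maps that
            # a deep He-initialized stack produces, avoiding the violent
            # first steps that kill ReLU units
            pred.w[...] = 0.0
            self.preds.append(pred)
            if s < stacks - 1:
                self.merge_feat.append(
                    Conv2d(self.head_channels, channels, 1, rng)
                )
                self.merge_pred.append(Conv2d(n_out, channels, 1, rng))

    def forward(self, x: np.ndarray) -> list:
        """Input (B, 1, H, W) -> list of (B, n_out, H, W), one per stack."""
        x = np.asarray(x, dtype=np.float32)
        B, C, H, W = x.shape
        if H % 2**self.depth or W % 2**self.depth:
            raise ValueError(
                f"input size {H}x{W} not divisible by 2^depth = {2**self.depth}"
            )
        f = self.stem_res.forward(self.stem_relu.forward(self.stem_conv.forward(x)))
        outs = []
        self._f_in = []
        for s in range(self.stacks):
            self._f_in.append(f)
            feat = self.posts[s].forward(self.hgs[s].forward(f))
            head = self.head_relus[s].forward(self.heads[s].forward(feat))
            pred = self.preds[s].forward(head)
            outs.append(pred)
            if s < self.stacks - 1:
                f = (
                    f
                    + self.merge_feat[s].forward(head)
                    + self.merge_pred[s].forward(pred)
                )
        return outs

    def backward(self, douts: list) -> None:
        """Accumulate parameter gradients from per-stack output gradients."""
        df = None
        for s in reversed(range(self.stacks)):
            dpred = douts[s].copy()
            dhead = None
            if s < self.stacks - 1:
                dpred += self.merge_pred[s].backward(df)
                dhead = self.merge_feat[s].backward(df)
            dh = self.preds[s].backward(dpred)
            if dhead is not None:
                dh = dh + dhead
            d = self.heads[s].backward(self.head_relus[s].backward(dh))
            dhg = self.posts[s].backward(d)
            dstack = self.hgs[s].backward(dhg)
            df = dstack + df if s < self.stacks - 1 else dstack
        self.stem_conv.backward(
            self.stem_relu.backward(self.stem_res.backward(df))
        )

    def convs(self):
        yield self.stem_conv
        yield from self.stem_res.convs()
        for s in range(self.stacks):
            yield from self.hgs[s].convs()
            yield from self.posts[s].convs()
            yield self.heads[s]
            yield self.preds[s]
            if s < self.stacks - 1:
                yield self.merge_feat[s]
                yield self.merge_pred[s]

    def zero_grad(self):
        for c in self.convs():
            c.zero_grad()

    # -------------------------------------------------------- serialization
    def state_arrays(self) -> dict:
        out = {}
        for i, c in enumerate(self.convs()):
            out[f"w{i}"] = c.w
            out[f"b{i}"] = c.b
        return out

    def load_state_arrays(self, arrays: dict) -> None:
        for i, c in enumerate(self.convs()):
            c.w = np.asarray(arrays[f"w{i}"], dtype=np.float32).reshape(c.w.shape)
            c.b = np.asarray(arrays[f"b{i}"], dtype=np.float32).reshape(c.b.shape)


class Adam:
    def __init__(self, model: StackedHourglassNet, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state = [
            (np.zeros_like(c.w), np.zeros_like(c.w),
             np.zeros_like(c.b), np.zeros_like(c.b))
            for c in model.convs()
        ]

    def step(self):
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for c, (mw, vw, mb, vb) in zip(self.model.convs(), self.state):
            for p, g, m, v in ((c.w, c.dw, mw, vw), (c.b, c.db, mb, vb)):
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def mse_loss(preds: list, target: np.ndarray,
             channel_weights: np.ndarray | None = None) -> tuple:
    """(Weighted) mean-squared error over all stacks against one target.

    ``channel_weights`` rescales the per-channel squared error; the point
    heatmaps carry far less energy than the mask channel, so balancing
    them keeps the peaks from being drowned out of the gradient. Returns
    ``(loss, grads)`` with grads matching the per-stack prediction list.
    """
    target = np.asarray(target, dtype=np.float32)
    loss = 0.0
    grads = []
    n = target.size * len(preds)
    if channel_weights is not None:
        w = np.asarray(channel_weights, dtype=np.float32).reshape(1, -1, 1, 1)
    else:
        w = None
    for p in preds:
        diff = p - target
        sq = diff.astype(np.float64) ** 2
        if w is None:
            loss += float(sq.sum()) / n
            grads.append((2.0 / n) * diff)
        else:
            loss += float((sq * w).sum()) / n
            grads.append((2.0 / n) * (diff * w))
    return loss, grads
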