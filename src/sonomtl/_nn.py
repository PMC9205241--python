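"""Minimal convolutional-network primitives with explicit backprop.

Implements exactly the pieces the package's backbone needs — 2-D
convolution (im2col), batch normalization, ReLU, global average
pooling, fully connected layers, residual down-sampling blocks and the
Adam optimizer — on plain numpy arrays in (N, C, H, W) layout.  Every
layer caches what its backward pass needs; ``backward`` consumes the
gradient w.r.t. its output and returns the gradient w.r.t. its input,
accumulating parameter gradients in ``.grads``.

Keeping the graph explicit (rather than taped) is what lets Grad-CAM
stop the backward pass at an arbitrary stage output.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Layer:
    def params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """(name, value, grad) triples; grads are accumulated in-place."""
        return []

    def zero_grad(self) -> None:
        for _, _, g in self.params():
            g[...] = 0.0


class Conv2d(Layer):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = (k - 1) // 2
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (c_in * k * k))  # He initialization
        self.W = (rng.standard_normal((c_out, c_in * k * k)) * scale).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._x_shape: tuple[int, ...] | None = None

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._x_shape = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
        self._cols = cols
        out = cols @ self.W.T + self.b
        return np.ascontiguousarray(out.transpose(0, 2, 1).reshape(n, self.c_out, ho, wo))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, _, ho, wo = dout.shape
        k, s, p = self.k, self.stride, self.pad
        dflat = dout.reshape(n, self.c_out, ho * wo).transpose(0, 2, 1)
        self.dW += np.einsum("nic,nij->cj", dflat, self._cols, optimize=True)
        self.db += dout.sum(axis=(0, 2, 3))
        dcols = (dflat @ self.W).reshape(n, ho, wo, self.c_in, k, k)
        _, c, h, w = self._x_shape
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=DTYPE)
        self.beta = np.zeros(c, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * invstd[:, None, None]
        self._cache = (xhat, invstd.astype(DTYPE), train)
        return self.gamma[:, None, None] * xhat + self.beta[:, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, invstd, train = self._cache
        self.dgamma += (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta += dout.sum(axis=(0, 2, 3))
        g = self.gamma[:, None, None] * invstd[:, None, None]
        if not train:  # running stats are constants in eval mode
            return dout * g
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dsum = dout.sum(axis=(0, 2, 3))[:, None, None]
        dxhat_sum = (dout * xhat).sum(axis=(0, 2, 3))[:, None, None]
        return g * (dout - dsum / m - xhat * dxhat_sum / m)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(1.0 / d_in)
        self.W = (rng.standard_normal((d_out, d_in)) * scale).astype(DTYPE)
        self.b = np.zeros(d_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW += dout.T @ self._x
        self.db += dout.sum(axis=0)
        return dout @ self.W


class DownBlock(Layer):
    """Residual block halving the spatial size: conv-bn-relu-conv-bn plus a
    1x1 strided projection skip, then ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, stride=2, rng=rng)
        self.bn1 = BatchNorm2d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, stride=1, rng=rng)
        self.bn2 = BatchNorm2d(c_out)
        self.skip = Conv2d(c_in, c_out, 1, stride=2, rng=rng)
        self.bn_s = BatchNorm2d(c_out)
        self.relu_out = ReLU()

    def params(self):
        out = []
        for name, layer in [("conv1", self.conv1), ("bn1", self.bn1),
                            ("conv2", self.conv2), ("bn2", self.bn2),
                            ("skip", self.skip), ("bn_s", self.bn_s)]:
            out.extend((f"{name}.{p}", v, g) for p, v, g in layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        main = self.bn1.forward(self.conv1.forward(x), train)
        main = self.relu1.forward(main)
        main = self.bn2.forward(self.conv2.forward(main), train)
        short = self.bn_s.forward(self.skip.forward(x), train)
        return self.relu_out.forward(main + short)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dout)
        dmain = self.conv2.backward(self.bn2.backward(d))
        dmain = self.bn1.backward(self.relu1.backward(dmain))
        dx = self.conv1.backward(dmain)
        dx += self.skip.backward(self.bn_s.backward(d))
        return dx


class SmallResNet(Layer):
    """Four-stage residual CNN: stem conv plus three down-sampling residual
    blocks, ending in global average pooling.

    ``stage_outputs`` (post-ReLU activation maps, one per stage) are kept
    after each forward pass for Grad-CAM.
    """

    def __init__(self, widths: tuple[int, ...] = (8, 16, 32, 64),
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.widths = tuple(widths)
        self.stem_conv = Conv2d(1, widths[0], 3, stride=1, rng=rng)
        self.stem_bn = BatchNorm2d(widths[0])
        self.stem_relu = ReLU()
        self.blocks = [DownBlock(widths[i], widths[i + 1], rng) for i in range(len(widths) - 1)]
        self.feature_dim = widths[-1]
        self.stage_outputs: list[np.ndarray] = []
        self._gap_shape: tuple[int, ...] | None = None

    def params(self):
        out = [(f"stem_conv.{p}", v, g) for p, v, g in self.stem_conv.params()]
        out += [(f"stem_bn.{p}", v, g) for p, v, g in self.stem_bn.params()]
        for i, blk in enumerate(self.blocks):
            out += [(f"block{i}.{p}", v, g) for p, v, g in blk.params()]
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.stem_relu.forward(self.stem_bn.forward(self.stem_conv.forward(x), train))
        self.stage_outputs = [h]
        for blk in self.blocks:
            h = blk.forward(h, train)
            self.stage_outputs.append(h)
        self._gap_shape = h.shape
        return h.mean(axis=(2, 3))  # (N, feature_dim)

    def backward(self, dfeat: np.ndarray, stop_at_stage: int | None = None) -> np.ndarray:
        """Backprop from the pooled features.  If ``stop_at_stage`` is given,
        return the gradient w.r.t. that stage's output instead of the input."""
        n, c, h, w = self._gap_shape
        d = np.broadcast_to(dfeat[:, :, None, None] / (h * w), self._gap_shape).astype(DTYPE)
        if stop_at_stage == len(self.blocks):
            return d
        for i in range(len(self.blocks) - 1, -1, -1):
            d = self.blocks[i].backward(d)
            if stop_at_stage == i:
                return d
        return self.stem_conv.backward(self.stem_bn.backward(self.stem_relu.backward(d)))


class Adam:
    """Adam optimizer over the (name, value, grad) triples of a model."""

    def __init__(self, params: list[tuple[str, np.ndarray, np.ndarray]],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(v) for _, v, _ in params]
        self.v = [np.zeros_like(v) for _, v, _ in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for i, (_, val, grad) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * grad * grad
            val -= lr * (self.m[i] / bias1) / (np.sqrt(self.v[i] / bias2) + self.eps)
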