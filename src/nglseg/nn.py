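"""Minimal CNN engine (NHWC, float32) used by the segmentation models.

Implements exactly the layer vocabulary the architectures need — 3x3
same-padding convolution (+ReLU), batch normalization, 2x max pooling,
2x nearest-neighbor upsampling, channel-concatenation skip links, and a
1x1 sigmoid output convolution — with reverse-mode gradients and an Adam
optimizer.  Convolutions use im2col + BLAS matmul; the data-gradient pass
scatters per-tap gradients back with nine shifted adds, which is exact for
stride-1 same padding.

A network is a linear instruction list over these layers; skip links are
expressed as ('save', key) / ('concat', key) instructions so the backward
pass can route the concatenated gradient back to the save point.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """Base: parameter dict, gradient dict, forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col3(xp: np.ndarray) -> np.ndarray:
    """(N, H+2, W+2, C) padded input -> (N*H*W, 9*C) patch matrix."""
    n, hp, wp, c = xp.shape
    h, w = hp - 2, wp - 2
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    # win: (N, H, W, C, 3, 3) -> (N, H, W, 3, 3, C) to match W layout (kh, kw, cin)
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
    return cols.reshape(n * h * w, 9 * c)


class Conv3x3(Layer):
    """3x3 convolution, same padding, optional fused ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 relu: bool = True):
        super().__init__()
        std = np.sqrt(2.0 / (9 * cin))
        self.params["W"] = rng.normal(0.0, std, size=(9 * cin, cout)).astype(DTYPE)
        self.params["b"] = np.zeros(cout, dtype=DTYPE)
        self.cin, self.cout, self.relu = cin, cout, relu

    def forward(self, x, training):
        n, h, w, c = x.shape
        if c != self.cin:
            raise ValueError(f"conv expected {self.cin} channels, got {c}")
        xp = np.zeros((n, h + 2, w + 2, c), dtype=DTYPE)
        xp[:, 1:-1, 1:-1] = x
        cols = _im2col3(xp)
        out = cols @ self.params["W"] + self.params["b"]
        out = out.reshape(n, h, w, self.cout)
        if self.relu:
            np.maximum(out, 0.0, out=out)
        self._cache = (cols, out if self.relu else None, (n, h, w))
        return out

    def backward(self, dy):
        cols, relu_out, (n, h, w) = self._cache
        if self.relu:
            dy = dy * (relu_out > 0)
        dy_flat = dy.reshape(n * h * w, self.cout).astype(DTYPE)
        self.grads["W"] = cols.T @ dy_flat
        self.grads["b"] = dy_flat.sum(axis=0)
        dcols = dy_flat @ self.params["W"].T  # (N*H*W, 9*cin)
        dcols = dcols.reshape(n, h, w, 3, 3, self.cin)
        dxp = np.zeros((n, h + 2, w + 2, self.cin), dtype=DTYPE)
        for i in range(3):
            for j in range(3):
                dxp[:, i:i + h, j:j + w] += dcols[:, :, :, i, j]
        self._cache = None
        return dxp[:, 1:-1, 1:-1]


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(DTYPE)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat.astype(DTYPE), inv_std.astype(DTYPE), training)
        return (xhat * self.params["gamma"] + self.params["beta"]).astype(DTYPE)

    def backward(self, dy):
        xhat, inv_std, training = self._cache
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 1, 2)).astype(DTYPE)
        self.grads["beta"] = dy.sum(axis=(0, 1, 2)).astype(DTYPE)
        g = dy * self.params["gamma"]
        if not training:
            return (g * inv_std).astype(DTYPE)
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        dx = (g - g.mean(axis=(0, 1, 2))
              - xhat * (g * xhat).sum(axis=(0, 1, 2)) / m) * inv_std
        self._cache = None
        return dx.astype(DTYPE)


class MaxPool2(Layer):
    def forward(self, x, training):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max-pool needs even spatial dims, got {h}x{w}")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        xf = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
        idx = xf.argmax(axis=-1)
        out = np.take_along_axis(xf, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (n, h, w, c))
        return out

    def backward(self, dy):
        idx, (n, h, w, c) = self._cache
        dxf = np.zeros((n, h // 2, w // 2, c, 4), dtype=DTYPE)
        np.put_along_axis(dxf, idx[..., None], dy[..., None].astype(DTYPE), axis=-1)
        dx = dxf.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        self._cache = None
        return dx.reshape(n, h, w, c)


class Upsample2(Layer):
    """Parameter-free 2x nearest-neighbor upsampling."""

    def forward(self, x, training):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy):
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4)).astype(DTYPE)


class OutConv(Layer):
    """1x1 convolution to a single sigmoid channel.

    ``backward`` expects the gradient with respect to the pre-sigmoid
    logits (the loss module supplies it in closed form).
    """

    def __init__(self, cin: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(1.0 / cin)
        self.params["W"] = rng.normal(0.0, std, size=(cin, 1)).astype(DTYPE)
        self.params["b"] = np.zeros(1, dtype=DTYPE)
        self.cin = cin

    def forward(self, x, training):
        z = x @ self.params["W"] + self.params["b"]
        # clamp logits so the sigmoid stays strictly inside (0, 1) in float32
        np.clip(z, -30.0, 30.0, out=z)
        y = 1.0 / (1.0 + np.exp(-z))
        self._cache = x
        return y[..., 0]

    def backward(self, dz):
        x = self._cache
        dz = dz[..., None].astype(DTYPE)
        n, h, w, _ = dz.shape
        x_flat = x.reshape(n * h * w, self.cin)
        dz_flat = dz.reshape(n * h * w, 1)
        self.grads["W"] = x_flat.T @ dz_flat
        self.grads["b"] = dz_flat.sum(axis=0)
        self._cache = None
        return (dz_flat @ self.params["W"].T).reshape(n, h, w, self.cin)


class Network:
    """Instruction-list network with skip routing.

    ``steps`` is a list of ('layer', Layer) | ('save', key) | ('concat', key);
    concat appends the saved feature's channels after the current ones.
    """

    def __init__(self, steps: list[tuple]):
        self.steps = steps
        self.layers = [obj for kind, obj in steps if kind == "layer"]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        cur = np.asarray(x, dtype=DTYPE)
        saved: dict = {}
        self._concat_split: dict = {}
        for kind, obj in self.steps:
            if kind == "layer":
                cur = obj.forward(cur, training)
            elif kind == "save":
                saved[obj] = cur
            elif kind == "concat":
                self._concat_split[obj] = cur.shape[-1]
                cur = np.concatenate([cur, saved[obj]], axis=-1)
            else:  # pragma: no cover
                raise ValueError(f"unknown step kind {kind!r}")
        return cur

    def backward(self, dz: np.ndarray) -> None:
        """Backpropagate from the gradient w.r.t. the output logits."""
        g = np.asarray(dz, dtype=DTYPE)
        skip_grads: dict = {}
        for kind, obj in reversed(self.steps):
            if kind == "layer":
                g = obj.backward(g)
            elif kind == "concat":
                c_main = self._concat_split[obj]
                skip_grads[obj] = g[..., c_main:]
                g = np.ascontiguousarray(g[..., :c_main])
            elif kind == "save":
                if obj in skip_grads:
                    g = g + skip_grads.pop(obj)

    # -- parameter plumbing ---------------------------------------------

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]

    @property
    def n_parameters(self) -> int:
        return int(sum(layer.params[name].size for layer, name in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                state[f"{i}.{name}"] = arr.copy()
            if isinstance(layer, BatchNorm):
                state[f"{i}.running_mean"] = layer.running_mean.copy()
                state[f"{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = state[f"{i}.{name}"].copy()
            if isinstance(layer, BatchNorm):
                layer.running_mean = state[f"{i}.running_mean"].copy()
                layer.running_var = state[f"{i}.running_var"].copy()


class Adam:
    def __init__(self, network: Network, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.network = network
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for j, (layer, name) in enumerate(network.parameters()):
            self.m[j] = np.zeros_like(layer.params[name])
            self.v[j] = np.zeros_like(layer.params[name])

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1 ** self.t
        corr2 = 1 - b2 ** self.t
        for j, (layer, name) in enumerate(self.network.parameters()):
            g = layer.grads.get(name)
            if g is None:
                continue
            self.m[j] = b1 * self.m[j] + (1 - b1) * g
            self.v[j] = b2 * self.v[j] + (1 - b2) * g * g
            mhat = self.m[j] / corr1
            vhat = self.v[j] / corr2
            layer.params[name] -= (self.lr * mhat
                                   / (np.sqrt(vhat) + self.eps)).astype(DTYPE)
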