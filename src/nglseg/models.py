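"""Encoder-decoder segmentation architectures and the trainable estimator.

Six networks are built from a symbolic layer sequence (codes C{f}, BN, MP,
UP, SAVE{i}/CAT{i} skip pairs, Out):

================  =============  =====  ========================================
name              pooling depth  skips  notes
================  =============  =====  ========================================
``segnet``        5              0      canonical 13 + 13 convolution plan
``unet``          4              4      two convs per level, concat skips
``3l_sn``         3              0      shallow variant, widths 64/128/256
``3l_usn``        3              3      3l_sn + concat skip at every level
``2l_usn``        2              2      widths 64/128
``2l_conv_usn``   2              2      2l_usn + one extra C+BN at bottleneck
================  =============  =====  ========================================

Every convolution is 3x3/same/ReLU followed by batch normalization;
upsampling is parameter-free 2x nearest-neighbor; the output layer is a
1x1 convolution with a sigmoid giving a per-pixel target probability.
Inputs must be scaled to [0, 1] and have spatial dims divisible by
2**pooling_depth.  Reducing the pooling depth (the 3L/2L variants)
preserves tiny-target evidence that deeper encoders pool away, and the
skip concatenations restore spatial detail lost across the bottleneck.

``width_scale`` shrinks every filter width proportionally (floor 4); it is
the knob desk-scale experiments use to keep training cheap while keeping
the architecture shape — see docs/methods.md.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .losses import LossConfig

MODEL_NAMES = ("segnet", "unet", "3l_sn", "3l_usn", "2l_usn", "2l_conv_usn")

_POOLING_DEPTH = {"segnet": 5, "unet": 4, "3l_sn": 3, "3l_usn": 3,
                  "2l_usn": 2, "2l_conv_usn": 2}


@dataclass
class ArchitectureSpec:
    """Symbolic plan a trainable network is built from (JSON-serializable)."""

    name: str
    layer_sequence: list[str]
    pooling_depth: int
    skip_pairs: list[tuple[int, int]]
    input_channels: int = 3
    width_scale: float = 1.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        d = json.loads(text)
        d["skip_pairs"] = [tuple(p) for p in d["skip_pairs"]]
        return cls(**d)


def _w(width: int, scale: float) -> int:
    return max(4, int(round(width * scale)))


def _conv_block(widths: list[int]) -> list[str]:
    seq = []
    for f in widths:
        seq += [f"C{f}", "BN"]
    return seq


def _layer_codes(name: str, scale: float) -> tuple[list[str], list[tuple[int, int]]]:
    s = lambda w: _w(w, scale)  # noqa: E731
    if name == "segnet":
        enc = [[64, 64], [128, 128], [256, 256, 256], [512, 512, 512], [512, 512, 512]]
        dec = [[512, 512, 512], [512, 512, 256], [256, 256, 128], [128, 64], [64, 64]]
        seq: list[str] = []
        for block in enc:
            seq += _conv_block([s(f) for f in block]) + ["MP"]
        for block in dec:
            seq += ["UP"] + _conv_block([s(f) for f in block])
        return seq + ["Out"], []
    if name == "unet":
        widths = [64, 128, 256, 512]
        seq = []
        for lvl, f in enumerate(widths, start=1):
            seq += _conv_block([s(f), s(f)]) + [f"SAVE{lvl}", "MP"]
        seq += _conv_block([s(1024), s(1024)])
        for lvl, f in zip(range(4, 0, -1), reversed(widths)):
            seq += ["UP", f"CAT{lvl}"] + _conv_block([s(f), s(f)])
        return seq + ["Out"], [(1, 4), (2, 3), (3, 2), (4, 1)]
    if name in ("3l_sn", "3l_usn"):
        widths = [64, 128, 256]
        skip = name == "3l_usn"
        seq = []
        for lvl, f in enumerate(widths, start=1):
            seq += _conv_block([s(f), s(f)])
            if skip:
                seq += [f"SAVE{lvl}"]
            seq += ["MP"]
        for lvl, f in zip(range(3, 0, -1), reversed(widths)):
            seq += ["UP"]
            if skip:
                seq += [f"CAT{lvl}"]
            seq += _conv_block([s(f), s(f)])
        pairs = [(1, 3), (2, 2), (3, 1)] if skip else []
        return seq + ["Out"], pairs
    if name in ("2l_usn", "2l_conv_usn"):
        widths = [64, 128]
        seq = []
        for lvl, f in enumerate(widths, start=1):
            seq += _conv_block([s(f), s(f)]) + [f"SAVE{lvl}", "MP"]
        if name == "2l_conv_usn":
            seq += _conv_block([s(256)])  # extra C+BN pair at the bottleneck
        for lvl, f in zip(range(2, 0, -1), reversed(widths)):
            seq += ["UP", f"CAT{lvl}"] + _conv_block([s(f), s(f)])
        return seq + ["Out"], [(1, 2), (2, 1)]
    raise ValueError(f"unknown model name {name!r}; expected one of {MODEL_NAMES}")


class SegmentationNetwork:
    """Trainable map: (h, w, C) in [0,1] -> (h, w) scores in (0, 1)."""

    def __init__(self, spec: ArchitectureSpec, net: nn.Network):
        self.spec = spec
        self.net = net

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters

    def _check_shape(self, x: np.ndarray) -> None:
        div = 2 ** self.spec.pooling_depth
        h, w = x.shape[1], x.shape[2]
        if h % div or w % div:
            raise ValueError(
                f"{self.spec.name} needs spatial dims divisible by {div}, got {h}x{w}")
        if x.shape[3] != self.spec.input_channels:
            raise ValueError(
                f"expected {self.spec.input_channels} channels, got {x.shape[3]}")

    def forward(self, batch: np.ndarray, training: bool = False) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float32)
        if batch.ndim == 3:
            batch = batch[None]
        self._check_shape(batch)
        return self.net.forward(batch, training=training)

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        out = self.forward(np.asarray(patch)[None] if np.asarray(patch).ndim == 3
                           else patch)
        return out[0] if np.asarray(patch).ndim == 3 else out

    def save(self, path: str) -> None:
        np.savez(path, __spec__=np.frombuffer(self.spec.to_json().encode(), np.uint8),
                 **self.net.state_dict())

    @classmethod
    def load(cls, path: str) -> "SegmentationNetwork":
        data = np.load(path)
        spec = ArchitectureSpec.from_json(bytes(data["__spec__"]).decode())
        network = cls.build(spec)
        network.net.load_state_dict({k: data[k] for k in data.files if k != "__spec__"})
        return network

    @classmethod
    def build(cls, spec: ArchitectureSpec, seed: int = 0) -> "SegmentationNetwork":
        rng = np.random.default_rng(seed)
        steps: list[tuple] = []
        cin = spec.input_channels
        saved_channels: dict[str, int] = {}
        for code in spec.layer_sequence:
            if re.fullmatch(r"C\d+", code):
                cout = int(code[1:])
                steps.append(("layer", nn.Conv3x3(cin, cout, rng, relu=True)))
                cin = cout
            elif code == "BN":
                steps.append(("layer", nn.BatchNorm(cin)))
            elif code == "MP":
                steps.append(("layer", nn.MaxPool2()))
            elif code == "UP":
                steps.append(("layer", nn.Upsample2()))
            elif code.startswith("SAVE"):
                saved_channels[code[4:]] = cin
                steps.append(("save", code[4:]))
            elif code.startswith("CAT"):
                key = code[3:]
                steps.append(("concat", key))
                cin = cin + saved_channels[key]
            elif code == "Out":
                steps.append(("layer", nn.OutConv(cin, rng)))
            else:
                raise ValueError(f"unknown layer code {code!r}")
        return cls(spec, nn.Network(steps))


def build_model(name: str, input_channels: int = 3, seed: int = 0,
                width_scale: float = 1.0) -> tuple[ArchitectureSpec, SegmentationNetwork]:
    """Construct one of the six named architectures with seeded init."""
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model name {name!r}; expected one of {MODEL_NAMES}")
    if input_channels not in (1, 3):
        raise ValueError("input_channels must be 1 or 3")
    seq, skip_pairs = _layer_codes(name, width_scale)
    spec = ArchitectureSpec(name=name, layer_sequence=seq,
                            pooling_depth=_POOLING_DEPTH[name],
                            skip_pairs=skip_pairs,
                            input_channels=input_channels,
                            width_scale=width_scale)
    return spec, SegmentationNetwork.build(spec, seed=seed)


def describe_architecture(spec: ArchitectureSpec) -> dict:
    """Layer-type census of a spec (convolutions exclude the 1x1 output)."""
    seq = spec.layer_sequence
    return {
        "name": spec.name,
        "conv": sum(1 for c in seq if re.fullmatch(r"C\d+", c)),
        "bn": sum(1 for c in seq if c == "BN"),
        "mp": sum(1 for c in seq if c == "MP"),
        "up": sum(1 for c in seq if c == "UP"),
        "skip": sum(1 for c in seq if c.startswith("CAT")),
        "out": sum(1 for c in seq if c == "Out"),
        "pooling_depth": spec.pooling_depth,
    }


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 8
    learning_rate: float = 1e-3
    patience: int = 10
    val_fraction: float = 0.1
    seed: int = 0


def fit_network(network: SegmentationNetwork, X: np.ndarray, y: np.ndarray,
                loss: LossConfig, train_cfg: TrainConfig) -> list[dict]:
    """Mini-batch Adam training; returns the per-epoch loss history and
    restores the parameters that achieved the best monitored loss.

    Monitors a held-out fraction of the patches when there are enough to
    split, else the training loss.  Raises on non-finite loss.
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    if X.ndim != 4 or y.ndim != 3 or X.shape[:3] != y.shape:
        raise ValueError(f"expected X (N,h,w,C) and aligned y (N,h,w); "
                         f"got {X.shape} / {y.shape}")
    n = X.shape[0]
    rng = np.random.default_rng(train_cfg.seed)

    n_val = int(round(train_cfg.val_fraction * n)) if n >= 5 else 0
    order = rng.permutation(n)
    val_idx, train_idx = order[:n_val], order[n_val:]
    Xtr, ytr = X[train_idx], y[train_idx]
    Xval, yval = X[val_idx], y[val_idx]

    opt = nn.Adam(network.net, lr=train_cfg.learning_rate)
    history: list[dict] = []
    best = np.inf
    best_state = network.net.state_dict()
    stale = 0
    for epoch in range(1, train_cfg.epochs + 1):
        perm = rng.permutation(len(Xtr))
        ep_loss = 0.0
        for start in range(0, len(Xtr), train_cfg.batch_size):
            sel = perm[start:start + train_cfg.batch_size]
            xb, yb = Xtr[sel], ytr[sel]
            y_hat = network.forward(xb, training=True)
            loss_val = loss.value(yb, y_hat)
            if not np.isfinite(loss_val):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}")
            dz = loss.grad_logits(yb, y_hat) / yb.size
            network.net.backward(dz)
            opt.step()
            ep_loss += loss_val * len(sel)
        ep_loss /= len(Xtr)

        if n_val:
            val_hat = network.forward(Xval, training=False)
            monitored = loss.value(yval, val_hat)
            history.append({"epoch": epoch, "train_loss": ep_loss,
                            "val_loss": monitored})
        else:
            monitored = ep_loss
            history.append({"epoch": epoch, "train_loss": ep_loss,
                            "val_loss": float("nan")})

        if monitored < best - 1e-9:
            best = monitored
            best_state = network.net.state_dict()
            stale = 0
        else:
            stale += 1
            if stale >= train_cfg.patience:
                break
    network.net.load_state_dict(best_state)
    return history


class SegmentationModel(BaseEstimator):
    """scikit-learn-style estimator over the six architectures.

    fit(X, y) with X of shape (n_patches, h, w, channels), values in [0, 1],
    and y binary (n_patches, h, w).  After fitting:

    - ``network_`` : the trained :class:`SegmentationNetwork`
    - ``spec_`` : the :class:`ArchitectureSpec` it was built from
    - ``history_`` : per-epoch loss records
    - ``n_parameters_`` : trainable parameter count
    """

    def __init__(self, arch: str = "3l_usn", loss: str = "bce", beta: float = 0.99,
                 epochs: int = 100, batch_size: int = 8, learning_rate: float = 1e-3,
                 patience: int = 10, val_fraction: float = 0.1,
                 width_scale: float = 1.0, random_state: int = 0):
        self.arch = arch
        self.loss = loss
        self.beta = beta
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.patience = patience
        self.val_fraction = val_fraction
        self.width_scale = width_scale
        self.random_state = random_state

    def _loss_config(self) -> LossConfig:
        return LossConfig(kind=self.loss, beta=self.beta)

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4:
            raise ValueError("X must be (n_patches, h, w, channels)")
        self.spec_, self.network_ = build_model(
            self.arch, input_channels=X.shape[3], seed=self.random_state,
            width_scale=self.width_scale)
        self.history_ = fit_network(
            self.network_, X, y, self._loss_config(),
            TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                        learning_rate=self.learning_rate, patience=self.patience,
                        val_fraction=self.val_fraction, seed=self.random_state))
        self.n_parameters_ = self.network_.n_parameters
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "network_"):
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=np.float32)
        out = np.empty(X.shape[:3], dtype=np.float32)
        step = max(1, self.batch_size)
        for start in range(0, X.shape[0], step):
            out[start:start + step] = self.network_.forward(X[start:start + step])
        return out

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        """Pixel accuracy at the 0.5 threshold (sklearn convention)."""
        pred = self.predict(X)
        return float((pred == np.asarray(y)).mean())
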