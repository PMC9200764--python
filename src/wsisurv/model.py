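"""The convolutional risk predictor and its attention fusion.

The network maps a normalized RGB patch to a single scalar risk (a deep
proportional-hazards log-risk).  Layers are implemented directly on numpy
with explicit backward passes, so the whole model trains on a CPU without
a deep-learning runtime.

Attention follows the gated-fusion design: from an intermediate feature
map F (N, D, H, W), a channel gate sigmoid(spatial mean per channel) and a
spatial gate sigmoid(channel mean per pixel) rescale F, and the two gated
maps are summed:

    out = C_att(F) * F + S_att(F) * F.

The default gates are parameter-free, so enabling attention adds no
learnable parameters; a learnable 1x1-projection variant is available via
``attention_learnable=True``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = [
    "RiskModel",
    "UnsupportedBackboneError",
    "channel_attention",
    "spatial_attention",
    "attention_fuse",
    "predict_risk",
    "init_weights",
    "n_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

NAMED_BACKBONES = ("resnet18", "vgg11bn", "densenet121", "alexnet")


class UnsupportedBackboneError(ValueError):
    """Raised when a backbone is recognized but not available in this build."""


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# im2col plumbing
# ---------------------------------------------------------------------------

def _im2col(x, k, stride, pad):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    oh, ow = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n, oh * ow, c * k * k)
    return cols, oh, ow


def _col2im(dcols, x_shape, k, stride, pad, oh, ow):
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d[:, :, :, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Layer:
    name = "layer"

    def params(self) -> dict:
        return {}

    def grads(self) -> dict:
        return {}

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(_Layer):
    def __init__(self, cin, cout, k=3, stride=1, pad=1, name="conv", dtype=np.float64):
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        self.name = name
        self.W = np.zeros((cout, cin * k * k), dtype=dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {f"{self.name}.W": self.W, f"{self.name}.b": self.b}

    def grads(self):
        return {f"{self.name}.W": self.dW, f"{self.name}.b": self.db}

    def forward(self, x, train=False):
        self._x_shape = x.shape
        cols, oh, ow = _im2col(x, self.k, self.stride, self.pad)
        self._cols, self._oh, self._ow = cols, oh, ow
        out = cols @ self.W.T + self.b
        return out.transpose(0, 2, 1).reshape(x.shape[0], self.cout, oh, ow)

    def backward(self, dout):
        n = dout.shape[0]
        dflat = dout.reshape(n, self.cout, -1).transpose(0, 2, 1)
        self.dW[...] = np.tensordot(dflat, self._cols, axes=([0, 1], [0, 1]))
        self.db[...] = dflat.sum(axis=(0, 1))
        dcols = dflat @ self.W
        return _col2im(dcols, self._x_shape, self.k, self.stride, self.pad, self._oh, self._ow)


class ReLU(_Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(_Layer):
    """2x2 max pooling with stride 2 (even spatial dims required)."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._arg = r.argmax(axis=-1)
        self._x_shape = x.shape
        return r.max(axis=-1)

    def backward(self, dout):
        n, c, h, w = self._x_shape
        dr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dr, self._arg[..., None], dout[..., None], axis=-1)
        return dr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class GlobalAvgPool(_Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Linear(_Layer):
    def __init__(self, fin, fout, name="fc", dtype=np.float64):
        self.name = name
        self.W = np.zeros((fout, fin), dtype=dtype)
        self.b = np.zeros(fout, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {f"{self.name}.W": self.W, f"{self.name}.b": self.b}

    def grads(self):
        return {f"{self.name}.W": self.dW, f"{self.name}.b": self.db}

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout):
        self.dW[...] = dout.T @ self._x
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W


class AttentionFuse(_Layer):
    """Channel- and spatial-gated fusion of a feature map with itself."""

    def __init__(self, channels=None, learnable=False, name="att", dtype=np.float64):
        self.learnable = bool(learnable)
        self.name = name
        if self.learnable:
            if channels is None:
                raise ValueError("learnable attention needs the channel count")
            self.Wc = np.zeros((channels, channels), dtype=dtype)
            self.Ws = np.zeros((channels, channels), dtype=dtype)
            self.dWc = np.zeros_like(self.Wc)
            self.dWs = np.zeros_like(self.Ws)

    def params(self):
        if not self.learnable:
            return {}
        return {f"{self.name}.Wc": self.Wc, f"{self.name}.Ws": self.Ws}

    def grads(self):
        if not self.learnable:
            return {}
        return {f"{self.name}.Wc": self.dWc, f"{self.name}.Ws": self.dWs}

    def forward(self, x, train=False):
        n, d, h, w = x.shape
        self._x = x
        if self.learnable:
            yc = np.einsum("dc,nchw->ndhw", self.Wc, x)
            ys = np.einsum("dc,nchw->ndhw", self.Ws, x)
        else:
            yc = ys = x
        self._mc = yc.mean(axis=(2, 3))          # (n, d)
        self._ms = ys.mean(axis=1)               # (n, h, w)
        self._c = _sigmoid(self._mc)
        self._s = _sigmoid(self._ms)
        return self._c[:, :, None, None] * x + self._s[:, None, :, :] * x

    def backward(self, dout):
        x, c, s = self._x, self._c, self._s
        n, d, h, w = x.shape
        dx = dout * (c[:, :, None, None] + s[:, None, :, :])
        dc = (dout * x).sum(axis=(2, 3))                       # (n, d)
        ds = (dout * x).sum(axis=1)                            # (n, h, w)
        gmc = dc * c * (1 - c)             # d loss / d mc, (n, d)
        gms = ds * s * (1 - s)             # d loss / d ms, (n, h, w)
        if self.learnable:
            xbar = x.mean(axis=(2, 3))                                   # (n, c)
            self.dWc[...] = np.einsum("nd,nc->dc", gmc, xbar)
            self.dWs[...] = np.tile(np.einsum("nhw,nchw->c", gms, x) / d, (d, 1))
            dx += (gmc @ self.Wc)[:, :, None, None] / (h * w)
            dx += gms[:, None, :, :] * self.Ws.mean(axis=0)[None, :, None, None]
        else:
            dx += np.broadcast_to(gmc[:, :, None, None] / (h * w), x.shape)
            dx += np.broadcast_to(gms[:, None, :, :] / d, x.shape)
        return dx


# ---------------------------------------------------------------------------
# risk model
# ---------------------------------------------------------------------------

class RiskModel:
    """Patch -> scalar risk network with optional attention fusion.

    The ``tiny`` backbone (three conv/ReLU/pool blocks, feature dimension
    64) is the built-in CPU backbone; the named large backbones
    (resnet18, vgg11bn, densenet121, alexnet) are recognized config values
    that require a deep-learning runtime with pretrained architectures and
    raise :class:`UnsupportedBackboneError` in this build.
    """

    def __init__(self, backbone: str = "tiny", attention_enabled: bool = True,
                 attention_learnable: bool = False, input_size: int = 64,
                 dtype=np.float32):
        if backbone in NAMED_BACKBONES:
            raise UnsupportedBackboneError(
                f"backbone {backbone!r} requires a deep-learning runtime with "
                f"pretrained architectures; this build provides the 'tiny' backbone"
            )
        if backbone != "tiny":
            raise ValueError(f"unknown backbone {backbone!r}")
        if input_size % 8 != 0 or input_size < 16:
            raise ValueError("input_size must be a multiple of 8 and >= 16")
        self.backbone_name = backbone
        self.attention_enabled = bool(attention_enabled)
        self.attention_learnable = bool(attention_learnable)
        self.input_size = int(input_size)
        self.feature_dim = 64
        self.dtype = np.dtype(dtype)

        channels = (16, 32, 64)
        layers = []
        cin = 3
        for i, cout in enumerate(channels):
            layers += [Conv2d(cin, cout, name=f"conv{i + 1}", dtype=self.dtype), ReLU(), MaxPool2()]
            cin = cout
        if self.attention_enabled:
            layers.append(AttentionFuse(channels=cin, learnable=attention_learnable, dtype=self.dtype))
        layers += [
            GlobalAvgPool(),
            Linear(cin, self.feature_dim, name="fc1", dtype=self.dtype),
            ReLU(),
            Linear(self.feature_dim, 1, name="fc2", dtype=self.dtype),
        ]
        self.layers = layers

    # -- parameter bookkeeping ------------------------------------------------

    def parameters(self) -> dict:
        out = {}
        for layer in self.layers:
            out.update(layer.params())
        return out

    def gradients(self) -> dict:
        out = {}
        for layer in self.layers:
            out.update(layer.grads())
        return out

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict) -> None:
        params = self.parameters()
        if set(params) != set(state):
            raise ValueError("state dict does not match model parameters")
        for k, v in params.items():
            v[...] = state[k]

    @property
    def config(self) -> dict:
        return {
            "backbone": self.backbone_name,
            "attention_enabled": self.attention_enabled,
            "attention_learnable": self.attention_learnable,
            "input_size": self.input_size,
            "dtype": self.dtype.name,
        }

    # -- passes ---------------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map (N, 3, H, W) normalized patches to (N,) risks."""
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError("expected an (N, 3, H, W) batch")
        out = x.astype(self.dtype, copy=False)
        for layer in self.layers:
            out = layer.forward(out, train=train)
        out = out[:, 0].astype(np.float64)
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("non-finite activations in risk head")
        return out

    def backward(self, drisk: np.ndarray) -> np.ndarray:
        dout = np.asarray(drisk, dtype=self.dtype)[:, None]
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def __call__(self, x, train=False):
        return self.forward(x, train=train)


# ---------------------------------------------------------------------------
# functional attention API (thin wrappers over AttentionFuse semantics)
# ---------------------------------------------------------------------------

def _as_chw(F):
    F = np.asarray(F, dtype=float)
    if F.ndim != 3:
        raise ValueError("expected an H x W x D feature map")
    if not np.all(np.isfinite(F)):
        raise ValueError("feature map must be finite")
    return F


def channel_attention(F: np.ndarray) -> np.ndarray:
    """Channel gates: sigmoid of each channel's spatial mean -> (1, 1, D)."""
    F = _as_chw(F)
    return _sigmoid(F.mean(axis=(0, 1)))[None, None, :]


def spatial_attention(F: np.ndarray) -> np.ndarray:
    """Spatial gates: sigmoid of each pixel's channel mean -> (H, W, 1)."""
    F = _as_chw(F)
    return _sigmoid(F.mean(axis=2))[:, :, None]


def attention_fuse(F: np.ndarray) -> np.ndarray:
    """Gated fusion C_att(F) * F + S_att(F) * F, preserving shape."""
    F = _as_chw(F)
    return channel_attention(F) * F + spatial_attention(F) * F


# ---------------------------------------------------------------------------
# weights and persistence
# ---------------------------------------------------------------------------

def init_weights(model: RiskModel, seed: int = 0) -> RiskModel:
    """Initialize every learnable weight ~ N(0, 0.01^2), biases exactly 0."""
    rng = np.random.default_rng(seed)
    for name in sorted(model.parameters()):
        arr = model.parameters()[name]
        if name.endswith(".b"):
            arr[...] = 0.0
        else:
            arr[...] = rng.normal(0.0, 1e-2, size=arr.shape).astype(arr.dtype)
    return model


def n_parameters(model: RiskModel) -> int:
    return int(sum(v.size for v in model.parameters().values()))


def predict_risk(model: RiskModel, patch: np.ndarray) -> float | np.ndarray:
    """Score one normalized H x W x 3 patch (or an N x H x W x 3 batch)."""
    arr = np.asarray(patch, dtype=float)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    if arr.shape[1:3] != (model.input_size, model.input_size):
        raise ValueError(
            f"patch size {arr.shape[1:3]} does not match configured input "
            f"size {(model.input_size, model.input_size)}"
        )
    risks = model.forward(arr.transpose(0, 3, 1, 2), train=False)
    return float(risks[0]) if single else risks


def save_checkpoint(model: RiskModel, path, seed: int | None = None) -> None:
    """Persist config + weights (+ the training seed) as an .npz archive."""
    meta = dict(model.config)
    if seed is not None:
        meta["seed"] = seed
    arrays = {f"param:{k}": v for k, v in model.parameters().items()}
    np.savez(Path(path), __config__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> RiskModel:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__config__"]).decode())
        model = RiskModel(
            backbone=meta["backbone"],
            attention_enabled=meta["attention_enabled"],
            attention_learnable=meta["attention_learnable"],
            input_size=meta["input_size"],
            dtype=np.dtype(meta.get("dtype", "float32")),
        )
        state = {k[len("param:"):]: data[k] for k in data.files if k.startswith("param:")}
    model.load_state_dict(state)
    return model
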