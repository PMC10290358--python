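"""A compact convolutional classifier: two conv layers, two pooling layers,
one fully connected layer, softmax class probabilities.

The network is small enough that a pure-NumPy implementation trains in
seconds on a CPU, which keeps the whole pipeline dependency-light and
bit-reproducible.  Layer sequence::

    conv1 (same padding, ReLU) -> pool1 -> conv2 (same padding, ReLU)
        -> pool2 -> flatten -> fully connected -> softmax

Pooling is max or average (both selectable), kernel 3x3 and channel widths
(8, 16) by default.  Weight initialisation is a seeded uniform fan-in
scheme: each weight tensor is drawn from U(-1/sqrt(fan_in), +1/sqrt(fan_in))
with ``numpy.random.default_rng(spec.seed)``, biases start at zero; the
draw order is conv1, conv2, fully connected, so two builds from the same
spec are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

__all__ = ["ModelSpec", "ClassProbability", "CNNClassifier", "build_model"]

_CHECKPOINT_FORMAT = "reedcover-cnn-v1"


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters of the classifier."""

    tile_size: int = 32
    in_channels: int = 3
    conv_channels: tuple[int, int] = (8, 16)
    kernel_size: int = 3
    pooling: str = "max"
    pool_size: int = 2
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes != 2:
            raise ValueError("the classifier is binary: n_classes must be 2")
        if len(self.conv_channels) != 2 or min(self.conv_channels) < 1:
            raise ValueError("conv_channels must be two positive counts")
        if self.pooling not in ("max", "average"):
            raise ValueError(f"pooling must be 'max' or 'average', got {self.pooling!r}")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd (same padding)")
        down = self.pool_size**2
        if self.tile_size % down != 0 or self.tile_size < down:
            raise ValueError(
                f"tile_size {self.tile_size} is incompatible with two pooling "
                f"stages of size {self.pool_size}: it must be a positive "
                f"multiple of {down} (minimum admissible size {down})"
            )

    @property
    def feature_size(self) -> int:
        """Spatial side of the feature map after both pooling stages."""
        return self.tile_size // self.pool_size**2

    @property
    def flatten_length(self) -> int:
        """Input width of the fully connected layer."""
        return self.conv_channels[1] * self.feature_size**2


@dataclass(frozen=True)
class ClassProbability:
    """Softmax output for one tile; the two probabilities sum to one."""

    p_reed: float
    p_nonreed: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_reed <= 1.0 and 0.0 <= self.p_nonreed <= 1.0):
            raise ValueError("class probabilities must lie in [0, 1]")
        if abs(self.p_reed + self.p_nonreed - 1.0) > 1e-6:
            raise ValueError("class probabilities must sum to 1")


# -- low-level layers -------------------------------------------------------


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Zero-padded same-convolution patches: (N,H,W,C) -> (N,H,W,C*k*k)."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # cols: (N, H, W, C, k, k); flatten channel-major to match weight layout
    n, h, w = x.shape[:3]
    return np.ascontiguousarray(cols).reshape(n, h, w, -1)


def _conv_forward(x, weight, bias):
    """weight: (Cin, k, k, Cout) flattened as (Cin*k*k, Cout)."""
    k = round((weight.shape[0] // x.shape[3]) ** 0.5)
    cols = _im2col(x, k)
    out = cols @ weight + bias
    return out, cols


def _conv_backward(dout, cols, weight, x_shape, k):
    n, h, w, c = x_shape
    dw = cols.reshape(-1, cols.shape[-1]).T @ dout.reshape(-1, dout.shape[-1])
    db = dout.sum(axis=(0, 1, 2))
    dcols = (dout @ weight.T).reshape(n, h, w, c, k, k)
    p = k // 2
    dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=dout.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, :, i, j]
    return dxp[:, p : p + h, p : p + w, :], dw, db


def _pool_forward(x, size, mode):
    n, h, w, c = x.shape
    r = x.reshape(n, h // size, size, w // size, size, c)
    if mode == "max":
        out = r.max(axis=(2, 4))
    else:
        out = r.mean(axis=(2, 4))
    return out, r


def _pool_backward(dout, r, size, mode):
    n, hh, _, ww, _, c = r.shape
    if mode == "max":
        out = r.max(axis=(2, 4))
        mask = r == out[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4))
        dr = mask * (dout / counts)[:, :, None, :, None, :]
    else:
        dr = np.broadcast_to(
            (dout / size**2)[:, :, None, :, None, :], r.shape
        ).copy()
    return dr.reshape(n, hh * size, ww * size, c)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# -- the model ---------------------------------------------------------------


class CNNClassifier:
    """The fitted (or freshly initialised) two-conv/two-pool classifier.

    Parameters live in ``self.params``; ``W1``/``W2`` are stored flattened
    as (Cin*k*k, Cout) ready for the im2col matmul, ``Wfc`` as
    (flatten_length, n_classes).
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        k = spec.kernel_size
        c_in, (c1, c2) = spec.in_channels, spec.conv_channels

        def uniform_fan_in(fan_in, shape):
            bound = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-bound, bound, size=shape).astype(np.float64)

        self.params: dict[str, np.ndarray] = {
            "W1": uniform_fan_in(c_in * k * k, (c_in * k * k, c1)),
            "b1": np.zeros(c1),
            "W2": uniform_fan_in(c1 * k * k, (c1 * k * k, c2)),
            "b2": np.zeros(c2),
            "Wfc": uniform_fan_in(spec.flatten_length, (spec.flatten_length, spec.n_classes)),
            "bfc": np.zeros(spec.n_classes),
        }

    @property
    def parameter_count(self) -> int:
        return sum(p.size for p in self.params.values())

    # -- forward / backward --

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        expected = (self.spec.tile_size, self.spec.tile_size, self.spec.in_channels)
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4 or x.shape[1:] != expected:
            raise ValueError(
                f"expected tiles of shape {expected}, received {tuple(x.shape[1:])}"
            )
        if x.dtype == np.uint8:
            x = x.astype(np.float64) / 255.0
        return x.astype(np.float64, copy=False)

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Class probabilities (N, 2); optionally the backprop cache."""
        p = self.params
        s = self.spec
        z1, cols1 = _conv_forward(x, p["W1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        p1, r1 = _pool_forward(a1, s.pool_size, s.pooling)
        z2, cols2 = _conv_forward(p1, p["W2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        p2, r2 = _pool_forward(a2, s.pool_size, s.pooling)
        flat = p2.reshape(x.shape[0], -1)
        logits = flat @ p["Wfc"] + p["bfc"]
        probs = softmax(logits)
        if not want_cache:
            return probs
        cache = dict(x=x, z1=z1, cols1=cols1, r1=r1, p1=p1,
                     z2=z2, cols2=cols2, r2=r2, flat=flat, probs=probs)
        return probs, cache

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Mean cross-entropy over the batch and gradients for every parameter."""
        s = self.spec
        probs, cache = self.forward(x, want_cache=True)
        n = x.shape[0]
        eps = 1e-12
        loss = -np.log(probs[np.arange(n), y] + eps).mean()

        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads = {
            "Wfc": cache["flat"].T @ dlogits,
            "bfc": dlogits.sum(axis=0),
        }
        dflat = dlogits @ self.params["Wfc"].T
        f = s.feature_size
        dp2 = dflat.reshape(n, f, f, s.conv_channels[1])
        da2 = _pool_backward(dp2, cache["r2"], s.pool_size, s.pooling)
        dz2 = da2 * (cache["z2"] > 0)
        dp1, grads["W2"], grads["b2"] = _conv_backward(
            dz2, cache["cols2"], self.params["W2"], cache["p1"].shape, s.kernel_size
        )
        da1 = _pool_backward(dp1, cache["r1"], s.pool_size, s.pooling)
        dz1 = da1 * (cache["z1"] > 0)
        _, grads["W1"], grads["b1"] = _conv_backward(
            dz1, cache["cols1"], self.params["W1"], cache["x"].shape, s.kernel_size
        )
        return loss, grads

    # -- prediction --

    def predict_proba_array(self, tiles: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """(N, 2) softmax probabilities, column order (non_reed, reed)."""
        x = self._check_input(tiles)
        out = [self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
        return np.concatenate(out) if out else np.empty((0, 2))

    def predict_proba(self, tiles) -> list[ClassProbability]:
        """Per-tile class probabilities, order matching the input order."""
        if isinstance(tiles, (list, tuple)):
            tiles = np.stack([np.asarray(t) for t in tiles]) if tiles else np.empty((0,))
        probs = self.predict_proba_array(tiles)
        return [ClassProbability(p_reed=float(p[1]), p_nonreed=float(p[0])) for p in probs]

    # -- persistence --

    def save(self, path) -> None:
        """Single-file checkpoint: versioned header + spec JSON + parameters."""
        header = json.dumps({"format": _CHECKPOINT_FORMAT, "spec": asdict(self.spec)})
        np.savez(path, __header__=np.array(header), **self.params)

    @classmethod
    def load(cls, path) -> "CNNClassifier":
        with np.load(path) as data:
            header = json.loads(str(data["__header__"]))
            if header.get("format") != _CHECKPOINT_FORMAT:
                raise ValueError(f"unrecognised checkpoint format in {path}")
            spec_dict = header["spec"]
            spec_dict["conv_channels"] = tuple(spec_dict["conv_channels"])
            model = cls(ModelSpec(**spec_dict))
            for name in model.params:
                model.params[name] = data[name]
        return model


def build_model(spec: ModelSpec) -> CNNClassifier:
    """Construct the classifier with deterministic seeded initialisation."""
    return CNNClassifier(spec)
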