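"""Network definitions: a small sequential ConvNet and linear readouts.

The classifier follows the reference architecture of the study: three
convolutional layers (16/32/64 kernels of sizes 5/3/3, stride 1, no
padding), each followed by ReLU and 2x2 max pooling, then two 250-unit
fully connected ReLU layers, 40% dropout, and a linear classification
head.  A ``width_scale`` multiplier shrinks channel and unit counts
proportionally for desk-scale runs.

Everything is implemented directly on numpy arrays (NHWC layout) with
explicit forward/backward passes; convolution uses im2col so the heavy
lifting is a single matrix product per layer.  Layer activations can be
"tapped" (post-ReLU, pre-pool for conv layers) without altering the
computation; linear readout probes are trained on those taps with the
backbone frozen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

TAPS = ("conv1", "conv2", "conv3", "fc1", "fc2")


@dataclass(frozen=True)
class ArchitectureSpec:
    conv_channels: tuple[int, ...] = (16, 32, 64)
    conv_kernels: tuple[int, ...] = (5, 3, 3)
    fc_sizes: tuple[int, ...] = (250, 250)
    dropout_rate: float = 0.4
    n_classes: int = 1600
    width_scale: float = 1.0

    def __post_init__(self):
        if len(self.conv_channels) != len(self.conv_kernels):
            raise ValueError("conv channel and kernel lists must match")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    def scaled_channels(self):
        return [max(2, int(round(c * self.width_scale))) for c in self.conv_channels]

    def scaled_fc(self):
        return [max(4, int(round(f * self.width_scale))) for f in self.fc_sizes]


@dataclass(frozen=True)
class ReadoutSpec:
    tap_layer: str
    n_classes: int

    def __post_init__(self):
        if self.tap_layer not in TAPS:
            raise ValueError(f"tap_layer must be one of {TAPS}")


# ---------------------------------------------------------------------------
# layers


class Conv2D:
    def __init__(self, c_in, c_out, k, rng, first=False):
        fan_in = c_in * k * k
        # W flattens as (c_in, k, k), matching the sliding-window layout
        self.W = (rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self.first = first

    def forward(self, x, train=False):
        k = self.k
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
        # win: (N, oh, ow, C, k, k); flatten trailing (C, k, k)
        cols = np.ascontiguousarray(win).reshape(
            x.shape[0], win.shape[1], win.shape[2], -1
        )
        self._x_shape = x.shape
        self._cols = cols if train else None
        return cols @ self.W.T + self.b

    def backward(self, dout):
        N, oh, ow, _ = dout.shape
        d2 = dout.reshape(-1, self.c_out)
        c2 = self._cols.reshape(-1, self.W.shape[1])
        self.dW = (d2.T @ c2).astype(np.float32)
        self.db = d2.sum(axis=0).astype(np.float32)
        self._cols = None
        if self.first:  # input gradient is never consumed
            return None
        k = self.k
        Wk = self.W.reshape(self.c_out, self.c_in, k, k)
        dx = np.zeros(self._x_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dx[:, i : i + oh, j : j + ow, :] += dout @ Wk[:, :, i, j]
        return dx

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class ReLU:
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2:
    def forward(self, x, train=False):
        a = x[:, 0::2, 0::2, :]
        b = x[:, 0::2, 1::2, :]
        c = x[:, 1::2, 0::2, :]
        d = x[:, 1::2, 1::2, :]
        out = np.maximum(np.maximum(a, b), np.maximum(c, d))
        if train:
            self._quads = (a, b, c, d)
            self._out = out
            self._shape = x.shape
        return out

    def backward(self, dout):
        # split gradient evenly across ties (deterministic subgradient)
        masks = [(q == self._out).astype(np.float32) for q in self._quads]
        cnt = masks[0] + masks[1] + masks[2] + masks[3]
        g = (dout / cnt).astype(np.float32)
        dx = np.zeros(self._shape, dtype=np.float32)
        dx[:, 0::2, 0::2, :] = masks[0] * g
        dx[:, 0::2, 1::2, :] = masks[1] * g
        dx[:, 1::2, 0::2, :] = masks[2] * g
        dx[:, 1::2, 1::2, :] = masks[3] * g
        self._quads = self._out = None
        return dx


class Flatten:
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense:
    def __init__(self, n_in, n_out, rng):
        self.W = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(
            np.float32
        )
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        self._x = None
        return dout @ self.W.T

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class Dropout:
    def __init__(self, rate):
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = self.rng.random(x.shape, dtype=np.float32) >= self.rate
        self._mask = keep.astype(np.float32) / np.float32(1 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


# ---------------------------------------------------------------------------
# the classifier


class ConvClassifier:
    """Sequential ConvNet with named activation taps.

    Taps are pure reads: requesting them never changes the computation.
    """

    def __init__(self, spec: ArchitectureSpec, input_size: tuple[int, int], seed: int = 0):
        H, W = input_size
        chans = spec.scaled_channels()
        fcs = spec.scaled_fc()
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.input_size = (H, W)
        self.seed = seed

        self.layers: list = []
        self.tap_points: dict[str, int] = {}
        c_in, h, w = 3, H, W
        for li, (c, k) in enumerate(zip(chans, spec.conv_kernels), start=1):
            h, w = h - k + 1, w - k + 1
            if h < 2 or w < 2:
                raise ValueError(
                    f"input {input_size} too small for conv{li} (k={k})"
                )
            self.layers.append(Conv2D(c_in, c, k, rng, first=(li == 1)))
            self.layers.append(ReLU())
            self.tap_points[f"conv{li}"] = len(self.layers) - 1
            if h % 2 or w % 2:
                raise ValueError(
                    f"feature map {h}x{w} before pool {li} is odd; "
                    "choose an input size surviving three 2x2 pools"
                )
            self.layers.append(MaxPool2())
            h, w, c_in = h // 2, w // 2, c
        self.layers.append(Flatten())
        n = h * w * c_in
        for fi, f in enumerate(fcs, start=1):
            self.layers.append(Dense(n, f, rng))
            self.layers.append(ReLU())
            self.tap_points[f"fc{fi}"] = len(self.layers) - 1
            n = f
        self.dropout = Dropout(spec.dropout_rate)
        self.layers.append(self.dropout)
        self.head = Dense(n, spec.n_classes, rng)
        self.layers.append(self.head)

    # -- execution ---------------------------------------------------------

    def forward(self, x, train=False, taps=None):
        """Return logits; if ``taps`` is a list, also a dict of activations."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        acts = {} if taps is not None else None
        inv = {v: k for k, v in self.tap_points.items()}
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, train=train)
            if acts is not None and i in inv and inv[i] in taps:
                acts[inv[i]] = x.reshape(x.shape[0], -1).copy()
        return (x, acts) if acts is not None else x

    def backward(self, dlogits):
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def parameters(self):
        out = []
        for i, layer in enumerate(self.layers):
            if hasattr(layer, "params"):
                for name, arr in layer.params().items():
                    out.append((f"layer{i}.{name}", layer, name, arr))
        return out

    def gradients(self):
        return {
            f"layer{i}.{name}": layer.grads()[name]
            for i, layer in enumerate(self.layers)
            if hasattr(layer, "grads")
            for name in layer.params()
        }

    def param_count(self) -> int:
        return sum(arr.size for _, _, _, arr in self.parameters())

    def state_dict(self):
        return {key: arr.copy() for key, _, _, arr in self.parameters()}

    def load_state_dict(self, state):
        for key, layer, name, arr in self.parameters():
            np.copyto(arr, state[key])

    def tap_dim(self, tap: str) -> int:
        """Flattened dimensionality of a tap's activation."""
        H, W = self.input_size
        x = np.zeros((1, H, W, 3), dtype=np.float32)
        _, acts = self.forward(x, taps=[tap])
        return acts[tap].shape[1]

    # -- persistence -------------------------------------------------------

    def save(self, path):
        path = Path(path)
        arch = {
            "conv_channels": list(self.spec.conv_channels),
            "conv_kernels": list(self.spec.conv_kernels),
            "fc_sizes": list(self.spec.fc_sizes),
            "dropout_rate": self.spec.dropout_rate,
            "n_classes": self.spec.n_classes,
            "width_scale": self.spec.width_scale,
            "input_size": list(self.input_size),
            "seed": self.seed,
        }
        np.savez(path, __arch__=json.dumps(arch), **self.state_dict())
        return path

    @staticmethod
    def load(path) -> "ConvClassifier":
        data = np.load(Path(path), allow_pickle=False)
        arch = json.loads(str(data["__arch__"]))
        spec = ArchitectureSpec(
            tuple(arch["conv_channels"]),
            tuple(arch["conv_kernels"]),
            tuple(arch["fc_sizes"]),
            arch["dropout_rate"],
            arch["n_classes"],
            arch["width_scale"],
        )
        model = ConvClassifier(spec, tuple(arch["input_size"]), arch["seed"])
        model.load_state_dict({k: data[k] for k in data.files if k != "__arch__"})
        return model


def build_classifier(
    spec: ArchitectureSpec, input_size: tuple[int, int], seed: int = 0
) -> ConvClassifier:
    return ConvClassifier(spec, input_size, seed)


# ---------------------------------------------------------------------------
# linear readouts


class LinearReadout:
    """A single linear map from a frozen tap to class logits."""

    def __init__(self, backbone: ConvClassifier, spec: ReadoutSpec, seed: int = 0):
        self.backbone = backbone
        self.spec = spec
        rng = np.random.default_rng(seed)
        n_in = backbone.tap_dim(spec.tap_layer)
        self.linear = Dense(n_in, spec.n_classes, rng)

    def features(self, x) -> np.ndarray:
        """Frozen-backbone tap activations (no gradient flows back)."""
        _, acts = self.backbone.forward(x, train=False, taps=[self.spec.tap_layer])
        return acts[self.spec.tap_layer]

    def forward_features(self, feats, train=False):
        return self.linear.forward(feats, train=train)

    def forward(self, x, train=False):
        return self.linear.forward(self.features(x), train=train)

    def backward(self, dlogits):
        # gradient stops at the tap: the backbone is never updated
        self.linear.backward(dlogits)

    def parameters(self):
        return [("readout.W", self.linear, "W", self.linear.W),
                ("readout.b", self.linear, "b", self.linear.b)]

    def gradients(self):
        return {"readout.W": self.linear.dW, "readout.b": self.linear.db}


def build_readout(
    backbone: ConvClassifier, spec: ReadoutSpec, seed: int = 0
) -> LinearReadout:
    return LinearReadout(backbone, spec, seed)
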