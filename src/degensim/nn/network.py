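"""Sequential classifier network with named weight tensors.

A :class:`Network` is an ordered stack of layers ending in a linear
``output`` layer whose class scores are turned into probabilities by a
softmax.  Weight tensors are addressed as ``"<layer>/<param>"`` (e.g.
``"conv_1/kernel"``, ``"dense_2/bias"``); names are stable across
save/load, which the injury engine relies on for its weight catalog.
"""

from __future__ import annotations

import copy

import numpy as np

from ..errors import InvalidArgumentError
from .layers import Conv2D, Dense, Dropout, Flatten, Layer, MaxPool2D


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Network:
    """Feed-forward classifier over image batches ``(n, H, W, C)``.

    Parameters
    ----------
    layers
        Ordered layer stack; the last parametric layer must be named
        ``"output"`` and be linear (softmax applied on top).
    input_shape
        ``(H, W, channels)`` expected by the first layer.
    penultimate
        Name of the layer whose post-activation output is read for
        representational analyses (default ``"dense_2"``).
    """

    def __init__(
        self,
        layers: list[Layer],
        input_shape: tuple[int, int, int],
        n_classes: int,
        penultimate: str = "dense_2",
        profile: str = "custom",
        seed: int | None = None,
        input_upscale: int = 1,
        metadata: dict | None = None,
    ):
        self.layers = layers
        self.input_shape = tuple(input_shape)
        self.n_classes = n_classes
        self.penultimate = penultimate
        self.profile = profile
        self.seed = seed
        self.input_upscale = input_upscale
        self.metadata = dict(metadata or {})
        names = [l.name for l in layers if l.params()]
        if len(names) != len(set(names)):
            raise InvalidArgumentError(f"duplicate layer names: {names}")

    # -- weight access -------------------------------------------------

    @property
    def weight_names(self) -> list[str]:
        """Ordered ``layer/param`` names; order is the catalog order."""
        out = []
        for layer in self.layers:
            for pname in layer.params():
                out.append(f"{layer.name}/{pname}")
        return out

    def get_weights(self) -> dict[str, np.ndarray]:
        return {
            f"{layer.name}/{p}": arr for layer in self.layers for p, arr in layer.params().items()
        }

    def set_weight(self, name: str, value: np.ndarray) -> None:
        layer_name, pname = name.split("/")
        for layer in self.layers:
            if layer.name == layer_name:
                current = layer.params()[pname]
                if current.shape != value.shape:
                    raise InvalidArgumentError(
                        f"shape mismatch for {name}: {current.shape} vs {value.shape}"
                    )
                setattr(layer, pname, np.asarray(value, dtype=float))
                return
        raise InvalidArgumentError(f"no such weight tensor: {name}")

    def copy(self) -> "Network":
        # drop forward caches first so the deepcopy is weights-only sized
        for layer in self.layers:
            if hasattr(layer, "_cache"):
                layer._cache = None
            if hasattr(layer, "_mask"):
                layer._mask = None
        return copy.deepcopy(self)

    # -- inference -----------------------------------------------------

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.input_upscale > 1:
            x = np.repeat(np.repeat(x, self.input_upscale, axis=1), self.input_upscale, axis=2)
        if x.shape[1:] != self.input_shape:
            raise InvalidArgumentError(
                f"input shape {x.shape[1:]} does not match model {self.input_shape}"
            )
        return x

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        capture: str | None = None,
    ):
        """Return logits; with ``capture`` also the named layer's output."""
        h = self._prepare(x)
        captured = None
        for layer in self.layers:
            h = layer.forward(h, training=training, rng=rng)
            if capture is not None and layer.name == capture:
                captured = h
        if capture is not None:
            if captured is None:
                raise InvalidArgumentError(f"no layer named {capture!r}")
            return h, captured
        return h

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Softmax class probabilities, dropout inactive."""
        outs = [softmax(self.forward(x[i : i + batch_size])) for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    def layer_activations(self, x: np.ndarray, layer_name: str, batch_size: int = 256) -> np.ndarray:
        """Post-activation outputs of the named layer (inference mode)."""
        outs = []
        for i in range(0, len(x), batch_size):
            _, act = self.forward(x[i : i + batch_size], capture=layer_name)
            outs.append(act.reshape(act.shape[0], -1))
        return np.concatenate(outs, axis=0)

    def backward(self, grad_logits: np.ndarray) -> None:
        g = grad_logits
        for layer in reversed(self.layers):
            g = layer.backward(g)


def build_small_cnn(
    n_classes: int,
    input_shape: tuple[int, int, int] = (16, 16, 1),
    dropout_rate: float = 0.3,
    seed: int = 0,
) -> Network:
    """Desk-scale reference network: 2 conv blocks + dense_1(64) + dense_2(32)."""
    h, w, c = input_shape
    if h % 4 or w % 4:
        raise InvalidArgumentError("small-cnn needs spatial dims divisible by 4 (two 2x2 pools)")
    rng = np.random.default_rng(seed)
    flat = (h // 4) * (w // 4) * 16
    layers: list[Layer] = [
        Conv2D("conv_1", c, 8, rng=rng),
        MaxPool2D(),
        Conv2D("conv_2", 8, 16, rng=rng),
        MaxPool2D(),
        Flatten(),
        Dense("dense_1", flat, 64, rng=rng),
        Dropout(dropout_rate),
        Dense("dense_2", 64, 32, rng=rng),
        Dropout(dropout_rate),
        Dense("output", 32, n_classes, activation=None, rng=rng),
    ]
    return Network(
        layers, input_shape, n_classes, penultimate="dense_2", profile="small-cnn", seed=seed
    )


# VGG-19 convolutional stack: 16 conv layers; 'M' = 2x2 max pool
VGG19_CONV_STACK = [
    64, 64, "M",
    128, 128, "M",
    256, 256, 256, 256, "M",
    512, 512, 512, 512, "M",
    512, 512, 512, 512, "M",
]


def build_vgg19(
    n_classes: int,
    conv_weights: dict[str, np.ndarray],
    dropout_rate: float = 0.3,
    seed: int = 0,
    input_size: int = 128,
    input_upscale: int = 4,
) -> Network:
    """VGG-19 topology with two 1000-neuron dense layers and a C-way softmax.

    ``conv_weights`` maps ``conv_i/kernel`` and ``conv_i/bias`` (i = 1..16)
    to pretrained arrays; dense and output layers are freshly initialized
    from ``seed``.  Inputs are upscaled ``input_upscale``x to
    ``input_size`` pixels before the first convolution.
    """
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    in_ch, size, conv_idx = 3, input_size, 0
    for item in VGG19_CONV_STACK:
        if item == "M":
            layers.append(MaxPool2D())
            size //= 2
        else:
            conv_idx += 1
            conv = Conv2D(f"conv_{conv_idx}", in_ch, int(item), rng=rng)
            for pname in ("kernel", "bias"):
                key = f"conv_{conv_idx}/{pname}"
                if key not in conv_weights:
                    raise InvalidArgumentError(f"pretrained weights missing tensor {key}")
                arr = np.asarray(conv_weights[key], dtype=float)
                if arr.shape != getattr(conv, pname).shape:
                    raise InvalidArgumentError(
                        f"pretrained {key} has shape {arr.shape}, "
                        f"expected {getattr(conv, pname).shape}"
                    )
                setattr(conv, pname, arr)
            layers.append(conv)
            in_ch = int(item)
    flat = size * size * 512
    layers += [
        Flatten(),
        Dense("dense_1", flat, 1000, rng=rng),
        Dropout(dropout_rate),
        Dense("dense_2", 1000, 1000, rng=rng),
        Dropout(dropout_rate),
        Dense("output", 1000, n_classes, activation=None, rng=rng),
    ]
    return Network(
        layers,
        (input_size, input_size, 3),
        n_classes,
        penultimate="dense_2",
        profile="vgg19-cifar100",
        seed=seed,
        input_upscale=input_upscale,
    )
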