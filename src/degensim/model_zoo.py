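"""Classifier profiles, training, replicate sets, and model persistence.

Two profiles are provided:

``small-cnn``
    Desk-scale reference network (two conv blocks, dense_1 = 64,
    dense_2 = 32, softmax output) trained from scratch on the synthetic
    hierarchical dataset.  All experiments and tests run on this profile.

``vgg19-cifar100``
    The full replication topology: VGG-19's 16 convolutional layers with
    user-supplied pretrained weights, two 1000-neuron dense layers and a
    C-way softmax head, 4x input upscaling to 128x128 pixels, trained with
    RMSprop at learning rate 3e-5 for 40 epochs with 30% dropout.
    Building and fine-tuning are supported; running the full training is
    GPU-scale and outside the test surface.

Training is end-to-end and sees only class labels — the superclass
structure never enters the optimizer, so any superclass organisation
found later in the representations is emergent.  All stochastic training
operations (initialization, shuffling, dropout masks) derive from the
config seed, making runs exactly repeatable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

from .errors import FormatError, InvalidArgumentError, MissingResourceError
from .hierarchy import ClassHierarchy
from .nn import (
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    MaxPool2D,
    Network,
    OPTIMIZERS,
    build_small_cnn,
    build_vgg19,
    softmax_cross_entropy,
)
from .synthetic_data import StimulusSet

PROFILES = ("small-cnn", "vgg19-cifar100")


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters for one training run.

    ``input_upscale`` is a nearest-neighbour integer upscaling applied at
    the model input (4x for the vgg19 profile, mirroring 32->128 pixels;
    1 for small-cnn, which consumes synthetic images at native size).
    """

    profile: str = "small-cnn"
    learning_rate: float = 1e-3
    optimizer: str = "rmsprop"
    epochs: int = 30
    dropout_rate: float = 0.3
    input_upscale: int = 1
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise InvalidArgumentError(f"unknown profile {self.profile!r}; choose from {PROFILES}")
        if self.optimizer not in OPTIMIZERS:
            raise InvalidArgumentError(f"unknown optimizer {self.optimizer!r}")
        if self.epochs < 0 or self.batch_size < 1:
            raise InvalidArgumentError("epochs must be >= 0 and batch_size >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise InvalidArgumentError("dropout_rate must be in [0, 1)")


def vgg19_cifar100_config(seed: int = 0) -> TrainingConfig:
    """The replication profile's reference hyperparameters."""
    return TrainingConfig(
        profile="vgg19-cifar100",
        learning_rate=3e-5,
        optimizer="rmsprop",
        epochs=40,
        dropout_rate=0.30,
        input_upscale=4,
        batch_size=64,
        seed=seed,
    )


def _load_conv_weights(path: str | Path) -> dict[str, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise MissingResourceError(f"pretrained conv weights not found: {path}")
    out: dict[str, np.ndarray] = {}
    with h5py.File(path, "r") as f:
        def visit(name, obj):
            if isinstance(obj, h5py.Dataset):
                out[name] = obj[()]
        f.visititems(visit)
    return out


def build_model(
    profile: str,
    hierarchy: ClassHierarchy,
    seed: int,
    *,
    dropout_rate: float = 0.3,
    input_shape: tuple[int, int, int] = (16, 16, 1),
    pretrained_conv_path: str | Path | None = None,
) -> Network:
    """Instantiate an untrained classifier for ``hierarchy.n_classes`` classes.

    The vgg19 profile refuses to build without a pretrained conv-weight
    file — silently random-initializing 16 conv layers would not be the
    replication topology.
    """
    n_classes = hierarchy.n_classes
    if profile == "small-cnn":
        return build_small_cnn(n_classes, input_shape=input_shape, dropout_rate=dropout_rate, seed=seed)
    if profile == "vgg19-cifar100":
        if pretrained_conv_path is None:
            raise MissingResourceError(
                "vgg19-cifar100 requires pretrained_conv_path (ImageNet conv weights); "
                "random conv initialization is not permitted for this profile"
            )
        conv_weights = _load_conv_weights(pretrained_conv_path)
        return build_vgg19(n_classes, conv_weights, dropout_rate=dropout_rate, seed=seed)
    raise InvalidArgumentError(f"unknown profile {profile!r}; choose from {PROFILES}")


def train_model(model: Network, train: StimulusSet, cfg: TrainingConfig) -> Network:
    """Train ``model`` in place with mini-batch gradient descent; returns it.

    Only class labels are consumed; the stimulus set's hierarchy is never
    read here.  Deterministic given ``cfg.seed``.
    """
    labels = np.asarray(train.labels)
    if labels.max(initial=0) >= model.n_classes or labels.min(initial=0) < 0:
        raise InvalidArgumentError(
            f"labels exceed model output dimension {model.n_classes}"
        )
    if cfg.epochs == 0:
        return model
    opt = OPTIMIZERS[cfg.optimizer](model, cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    n = len(train)
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            logits = model.forward(train.images[idx], training=True, rng=rng)
            _, grad = softmax_cross_entropy(logits, labels[idx])
            model.backward(grad)
            opt.step()
    return model


@dataclass
class ReplicateSet:
    """Trained replicate networks with their seeds and final test accuracies.

    No replicate is ever excluded post-training, however it performed.
    """

    models: list[Network]
    seeds: list[int]
    test_accuracies: list[float | None] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.models)


def replicate_seed(base_seed: int, replicate_index: int) -> int:
    """Derived training seed for one replicate: counter rule ``base + 1 + r``."""
    return int(base_seed) + 1 + int(replicate_index)


def train_replicates(
    n: int,
    train: StimulusSet,
    cfg: TrainingConfig,
    base_seed: int,
    *,
    test: StimulusSet | None = None,
    input_shape: tuple[int, int, int] | None = None,
    pretrained_conv_path: str | Path | None = None,
) -> ReplicateSet:
    """Train ``n`` independently initialized replicates with distinct seeds.

    small-cnn replicates re-initialize everything; vgg19 replicates share
    the pretrained conv weights and vary only dense/output initialization
    (and training randomness).
    """
    if n < 1:
        raise InvalidArgumentError(f"replicate count must be >= 1, got {n}")
    if input_shape is None:
        input_shape = train.images.shape[1:]
    models, seeds, accs = [], [], []
    for r in range(n):
        seed_r = replicate_seed(base_seed, r)
        model = build_model(
            cfg.profile,
            train.hierarchy,
            seed_r,
            dropout_rate=cfg.dropout_rate,
            input_shape=tuple(input_shape),
            pretrained_conv_path=pretrained_conv_path,
        )
        train_model(model, train, replace(cfg, seed=seed_r))
        acc = None
        if test is not None:
            probs = model.predict_proba(test.images)
            acc = float(np.mean(np.argmax(probs, axis=1) == test.labels))
        models.append(model)
        seeds.append(seed_r)
        accs.append(acc)
    return ReplicateSet(models=models, seeds=seeds, test_accuracies=accs)


# -- persistence -------------------------------------------------------


def _layer_spec(layer) -> dict:
    if isinstance(layer, Conv2D):
        kh, kw, cin, cout = layer.kernel.shape
        return {"type": "conv2d", "name": layer.name, "in": cin, "out": cout,
                "kernel_size": kh, "activation": layer.activation}
    if isinstance(layer, MaxPool2D):
        return {"type": "maxpool2d", "pool": layer.pool}
    if isinstance(layer, Flatten):
        return {"type": "flatten"}
    if isinstance(layer, Dense):
        fin, fout = layer.kernel.shape
        return {"type": "dense", "name": layer.name, "in": fin, "out": fout,
                "activation": layer.activation}
    if isinstance(layer, Dropout):
        return {"type": "dropout", "rate": layer.rate}
    raise InvalidArgumentError(f"unserializable layer {type(layer).__name__}")


def _layer_from_spec(spec: dict):
    t = spec["type"]
    if t == "conv2d":
        return Conv2D(spec["name"], spec["in"], spec["out"], kernel_size=spec["kernel_size"],
                      activation=spec["activation"])
    if t == "maxpool2d":
        return MaxPool2D(spec["pool"])
    if t == "flatten":
        return Flatten()
    if t == "dense":
        return Dense(spec["name"], spec["in"], spec["out"], activation=spec["activation"])
    if t == "dropout":
        return Dropout(spec["rate"])
    raise FormatError(f"unknown layer type {t!r} in model sidecar")


def save_model(model: Network, path: str | Path, metrics: dict | None = None) -> Path:
    """Write weights to HDF5 at ``path`` plus a ``.json`` architecture sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        for name, arr in model.get_weights().items():
            f.create_dataset(name, data=arr)
    sidecar = {
        "format": "degensim-model",
        "version": 1,
        "profile": model.profile,
        "seed": model.seed,
        "n_classes": model.n_classes,
        "input_shape": list(model.input_shape),
        "input_upscale": model.input_upscale,
        "penultimate": model.penultimate,
        "layers": [_layer_spec(l) for l in model.layers],
        "weight_names": model.weight_names,
        "metrics": metrics or {},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return path


def load_model(path: str | Path) -> Network:
    """Rebuild a model from :func:`save_model` output, weights bit-exact."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not path.exists() or not sidecar_path.exists():
        raise MissingResourceError(f"model file or sidecar missing for {path}")
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{sidecar_path}: invalid JSON ({exc})") from exc
    for field_name in ("format", "layers", "n_classes", "input_shape", "penultimate"):
        if field_name not in sidecar:
            raise FormatError(f"{sidecar_path}: missing field '{field_name}'")
    layers = [_layer_from_spec(s) for s in sidecar["layers"]]
    model = Network(
        layers,
        tuple(sidecar["input_shape"]),
        sidecar["n_classes"],
        penultimate=sidecar["penultimate"],
        profile=sidecar.get("profile", "custom"),
        seed=sidecar.get("seed"),
        input_upscale=sidecar.get("input_upscale", 1),
        metadata=sidecar.get("metrics", {}),
    )
    try:
        with h5py.File(path, "r") as f:
            for name in model.weight_names:
                model.set_weight(name, f[name][()])
    except (KeyError, OSError) as exc:
        raise FormatError(f"{path}: corrupt or incomplete weight file ({exc})") from exc
    return model
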