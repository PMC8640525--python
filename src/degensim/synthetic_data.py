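"""Hierarchical synthetic image datasets with CIFAR-100-like structure.

The generator emulates the *statistical* structure of CIFAR-100 that the
degeneration experiments depend on — balanced classes nested in balanced
superclasses, with images of classes in the same superclass more similar
to each other than to images from other superclasses — without shipping
or downloading any real image data.

Generative model
----------------
For each superclass ``s`` draw a prototype ``mu_s = 0.5 + blur(eta_s)``
with ``eta_s ~ N(0, sigma_sup^2)`` i.i.d. per pixel; for each class ``c``
in ``s`` draw ``mu_c = mu_s + blur(delta_c)`` with ``delta_c ~
N(0, sigma_cls^2)``; each image is ``clip(mu_c + eps, 0, 1)`` with
pixelwise noise ``eps ~ N(0, sigma_noise^2)``.  The box blur (radius 2)
gives prototypes local spatial correlation so convolutional features are
informative.  Requiring ``sigma_cls < sigma_sup`` makes superclass
structure dominate class structure, the prerequisite for the hierarchy
analyses downstream.

Seeding: the root seed spawns three fixed child streams — ``seed`` for
prototypes, ``seed + 1`` for train images, ``seed + 2`` for test images —
so the two splits are disjoint, independent draws and the whole dataset
is a pure function of the config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from scipy.ndimage import uniform_filter

from .errors import FormatError, InvalidArgumentError
from .hierarchy import ClassHierarchy, make_hierarchy

_BLUR_RADIUS = 2  # pixels; 5x5 box blur

MANIFEST_NAME = "manifest.json"
HIERARCHY_NAME = "hierarchy.csv"
TENSORS_NAME = "stimuli.h5"


@dataclass(frozen=True)
class StimulusSet:
    """A labeled image collection bound to a class hierarchy.

    ``images`` has shape ``(n, H, W, channels)`` with values in [0, 1];
    ``labels[i]`` is the class id of ``images[i]``.
    """

    images: np.ndarray
    labels: np.ndarray
    hierarchy: ClassHierarchy
    split_tag: str

    def __post_init__(self) -> None:
        if self.images.ndim != 4:
            raise InvalidArgumentError("images must be (n, H, W, channels)")
        if len(self.images) != len(self.labels):
            raise InvalidArgumentError("images and labels must have equal length")
        valid = set(self.hierarchy.class_ids)
        bad = set(np.unique(self.labels).tolist()) - valid
        if bad:
            raise InvalidArgumentError(f"labels not present in hierarchy: {sorted(bad)}")
        if self.split_tag not in ("train", "test"):
            raise InvalidArgumentError(f"split_tag must be train|test, got {self.split_tag!r}")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def superclass_labels(self) -> np.ndarray:
        """Superclass id per stimulus, derived from the hierarchy."""
        lut = np.array(
            [self.hierarchy.superclass_of[c] for c in self.hierarchy.class_ids], dtype=np.int64
        )
        return lut[self.labels]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the hierarchical image generator.

    Defaults are the desk-scale study conditions: 5 superclasses x 4
    classes, 16x16 single-channel images, 100 train / 50 test images per
    class, field scales (0.5, 0.15, 0.1).
    """

    n_superclasses: int = 5
    classes_per_superclass: int = 4
    images_per_class_train: int = 100
    images_per_class_test: int = 50
    image_size: int = 16
    channels: int = 1
    sigma_superclass: float = 0.5
    sigma_class: float = 0.15
    sigma_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_superclasses": self.n_superclasses,
            "classes_per_superclass": self.classes_per_superclass,
            "images_per_class_train": self.images_per_class_train,
            "images_per_class_test": self.images_per_class_test,
            "image_size": self.image_size,
            "channels": self.channels,
        }
        for name, value in counts.items():
            if value < 1:
                raise InvalidArgumentError(f"{name} must be >= 1, got {value}")
        if self.n_superclasses < 2:
            raise InvalidArgumentError("n_superclasses must be >= 2")
        for name in ("sigma_superclass", "sigma_class", "sigma_noise"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be non-negative")
        if not self.sigma_class < self.sigma_superclass:
            raise InvalidArgumentError(
                "sigma_class must be < sigma_superclass so superclass structure dominates"
            )

    @property
    def n_classes(self) -> int:
        return self.n_superclasses * self.classes_per_superclass


def _blur(field: np.ndarray) -> np.ndarray:
    # box blur over the two spatial axes only
    size = 2 * _BLUR_RADIUS + 1
    return uniform_filter(field, size=(size, size, 1), mode="wrap")


def class_prototypes(cfg: GeneratorConfig) -> tuple[np.ndarray, ClassHierarchy]:
    """Class prototype images ``mu_c``, shape ``(C, H, W, channels)``, unclipped.

    Exposed so the hierarchical-structure property (within-superclass
    prototype distances < between-superclass distances) can be asserted
    directly on the prototypes.
    """
    hierarchy = make_hierarchy(cfg.n_superclasses, cfg.classes_per_superclass)
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.image_size, cfg.image_size, cfg.channels)
    protos = np.empty((cfg.n_classes, *shape), dtype=np.float64)
    for s in range(cfg.n_superclasses):
        mu_s = 0.5 + _blur(rng.normal(0.0, cfg.sigma_superclass, size=shape))
        for c in hierarchy.classes_in(s):
            protos[c] = mu_s + _blur(rng.normal(0.0, cfg.sigma_class, size=shape))
    return protos, hierarchy


def _draw_split(
    protos: np.ndarray,
    hierarchy: ClassHierarchy,
    per_class: int,
    sigma_noise: float,
    rng: np.random.Generator,
    split_tag: str,
) -> StimulusSet:
    n_classes = len(protos)
    images = np.empty((n_classes * per_class, *protos.shape[1:]), dtype=np.float32)
    labels = np.empty(n_classes * per_class, dtype=np.int64)
    for c in range(n_classes):
        noise = rng.normal(0.0, sigma_noise, size=(per_class, *protos.shape[1:]))
        block = np.clip(protos[c][None] + noise, 0.0, 1.0)
        images[c * per_class : (c + 1) * per_class] = block.astype(np.float32)
        labels[c * per_class : (c + 1) * per_class] = c
    return StimulusSet(images=images, labels=labels, hierarchy=hierarchy, split_tag=split_tag)


def generate_dataset(cfg: GeneratorConfig) -> tuple[StimulusSet, StimulusSet]:
    """Generate the (train, test) splits for one config, deterministically."""
    protos, hierarchy = class_prototypes(cfg)
    train_rng = np.random.default_rng(cfg.seed + 1)
    test_rng = np.random.default_rng(cfg.seed + 2)
    train = _draw_split(
        protos, hierarchy, cfg.images_per_class_train, cfg.sigma_noise, train_rng, "train"
    )
    test = _draw_split(
        protos, hierarchy, cfg.images_per_class_test, cfg.sigma_noise, test_rng, "test"
    )
    return train, test


def write_hierarchy_csv(hierarchy: ClassHierarchy, path: Path) -> None:
    lines = ["class_id,superclass_id"]
    lines += [f"{c},{hierarchy.superclass_of[c]}" for c in hierarchy.class_ids]
    path.write_text("\n".join(lines) + "\n")


def read_hierarchy_csv(path: Path) -> ClassHierarchy:
    text = path.read_text().strip().splitlines()
    if not text or text[0].strip() != "class_id,superclass_id":
        raise FormatError(f"{path}: expected header 'class_id,superclass_id'")
    superclass_of: dict[int, int] = {}
    for line in text[1:]:
        c, s = line.split(",")
        superclass_of[int(c)] = int(s)
    return ClassHierarchy(class_ids=tuple(sorted(superclass_of)), superclass_of=superclass_of)


def write_dataset(
    sets: tuple[StimulusSet, StimulusSet],
    hierarchy: ClassHierarchy,
    directory: str | Path,
    config: GeneratorConfig | None = None,
) -> Path:
    """Serialize splits + hierarchy + manifest into ``directory``; returns it.

    Layout: ``hierarchy.csv`` (two-column text), ``stimuli.h5`` (images and
    labels per split), ``manifest.json`` (shapes, dtypes, split tags, and
    the generator config when available).  Round-trips bit-exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_hierarchy_csv(hierarchy, directory / HIERARCHY_NAME)
    splits: dict[str, dict] = {}
    with h5py.File(directory / TENSORS_NAME, "w") as f:
        for ss in sets:
            grp = f.create_group(ss.split_tag)
            grp.create_dataset("images", data=ss.images)
            grp.create_dataset("labels", data=ss.labels)
            splits[ss.split_tag] = {
                "n": len(ss),
                "image_shape": list(ss.images.shape[1:]),
                "dtype": str(ss.images.dtype),
            }
    manifest = {
        "format": "degensim-dataset",
        "version": 1,
        "splits": splits,
        "generator_config": dataclasses.asdict(config) if config is not None else None,
        "seed": config.seed if config is not None else None,
    }
    (directory / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2) + "\n")
    return directory


def read_dataset(directory: str | Path) -> tuple[tuple[StimulusSet, StimulusSet], ClassHierarchy]:
    """Inverse of :func:`write_dataset`; validates the manifest first."""
    directory = Path(directory)
    manifest_path = directory / MANIFEST_NAME
    if not manifest_path.exists():
        raise FormatError(f"{directory}: missing {MANIFEST_NAME}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{manifest_path}: invalid JSON ({exc})") from exc
    for field_name in ("format", "version", "splits"):
        if field_name not in manifest:
            raise FormatError(f"{manifest_path}: missing field '{field_name}'")
    hierarchy = read_hierarchy_csv(directory / HIERARCHY_NAME)
    tensor_path = directory / TENSORS_NAME
    if not tensor_path.exists():
        raise FormatError(f"{directory}: missing {TENSORS_NAME}")
    sets = []
    with h5py.File(tensor_path, "r") as f:
        for split_tag in ("train", "test"):
            if split_tag not in manifest["splits"]:
                raise FormatError(f"{manifest_path}: missing split '{split_tag}'")
            grp = f[split_tag]
            sets.append(
                StimulusSet(
                    images=grp["images"][()],
                    labels=grp["labels"][()],
                    hierarchy=hierarchy,
                    split_tag=split_tag,
                )
            )
    return (sets[0], sets[1]), hierarchy
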