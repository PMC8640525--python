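"""Shared fixtures: synthetic datasets and trained reference networks.

Everything is generated at test time from fixed seeds; nothing is read
from disk.  The expensive fixtures (a fully trained desk-scale network,
the full degeneration experiment) are session-scoped so the suite trains
each network exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

from degensim.experiment_runner import ExperimentConfig, run_experiment
from degensim.injury_engine import InjurySchedule
from degensim.model_zoo import TrainingConfig, build_model, train_model
from degensim.synthetic_data import GeneratorConfig, generate_dataset

DESK_SEED = 1


@pytest.fixture(scope="session")
def desk_cfg() -> GeneratorConfig:
    """Default desk-scale generator: 5 superclasses x 4 classes, 16x16."""
    return GeneratorConfig(seed=DESK_SEED)


@pytest.fixture(scope="session")
def desk_dataset(desk_cfg):
    return generate_dataset(desk_cfg)


@pytest.fixture(scope="session")
def hierarchy(desk_dataset):
    return desk_dataset[0].hierarchy


@pytest.fixture(scope="session")
def trained_model(desk_dataset, hierarchy):
    """small-cnn trained for the default 30 epochs on the desk dataset."""
    train, _ = desk_dataset
    model = build_model("small-cnn", hierarchy, seed=DESK_SEED)
    return train_model(model, train, TrainingConfig(seed=DESK_SEED, epochs=30))


@pytest.fixture(scope="session")
def tiny_dataset():
    """Much smaller dataset for fast functional tests."""
    cfg = GeneratorConfig(
        n_superclasses=2,
        classes_per_superclass=2,
        images_per_class_train=20,
        images_per_class_test=10,
        image_size=8,
        seed=3,
    )
    return generate_dataset(cfg), cfg


@pytest.fixture(scope="session")
def tiny_trained(tiny_dataset):
    (train, test), _ = tiny_dataset
    model = build_model("small-cnn", train.hierarchy, seed=3, input_shape=(8, 8, 1))
    return train_model(model, train, TrainingConfig(seed=3, epochs=5)), test


@pytest.fixture(scope="session")
def desk_experiment(tmp_path_factory):
    """The scaled-down degeneration study: 5 replicates, 0.005 steps to 0.5,
    7 RSA checkpoints."""
    cfg = ExperimentConfig(
        generator=GeneratorConfig(seed=DESK_SEED),
        training=TrainingConfig(seed=DESK_SEED, epochs=30),
        n_replicates=5,
        schedule=InjurySchedule(
            increment=0.005,
            max_fraction=0.5,
            rsa_checkpoints=(0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.5),
        ),
        base_seed=DESK_SEED,
        rsa_conditions_per_class=10,
        out_dir=str(tmp_path_factory.mktemp("desk_experiment")),
    )
    records, summaries, artifacts = run_experiment(cfg)
    return cfg, records, summaries, artifacts


def tiny_experiment_config(out_dir: str, seed: int = 5) -> ExperimentConfig:
    """Cheap end-to-end config used by determinism and export tests."""
    return ExperimentConfig(
        generator=GeneratorConfig(
            n_superclasses=3,
            classes_per_superclass=2,
            images_per_class_train=15,
            images_per_class_test=8,
            image_size=8,
            seed=seed,
        ),
        training=TrainingConfig(seed=seed, epochs=3),
        n_replicates=2,
        schedule=InjurySchedule(increment=0.25, max_fraction=1.0, rsa_checkpoints=(0.0, 0.5, 1.0)),
        base_seed=seed,
        rsa_conditions_per_class=5,
        out_dir=out_dir,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
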