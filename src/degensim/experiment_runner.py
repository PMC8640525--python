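"""Orchestration of the full degeneration experiment.

For each replicate network: train an uninjured baseline, compute its
reference RDMs (object- and superclass-level), then walk the cumulative
injury schedule — recording accuracy and within-superclass error at
every increment, and tau_A of the injured vs the *same* replicate's
uninjured RDM at each RSA checkpoint.  Replicate curves are averaged
into mean +/- SD summaries, yielding the degeneration,
representational-decay and error-structure curves.

Seeding: one base seed drives everything — the dataset generator uses
it directly, replicate r trains with ``base + 1 + r`` and is injured
with stream ``base + 100000 + r`` — so a run is a pure function of its
config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import injury_engine as inj
from .behavior_metrics import accuracy, predict_labels, within_superclass_error_rate
from .errors import DegensimError, InvalidArgumentError
from .model_zoo import TrainingConfig, build_model, train_model
from .rsa_metrics import RDM, build_rdm, compare_rdms, penultimate_activations, superclass_rdm
from .synthetic_data import GeneratorConfig, StimulusSet, generate_dataset, read_dataset

logger = logging.getLogger(__name__)

RECORDS_CSV_COLUMNS = [
    "replicate_id",
    "injured_fraction",
    "accuracy",
    "within_superclass_error_rate",
    "tau_a_object",
    "tau_a_superclass",
]

DEFAULT_CHECKPOINTS = (0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.5)


class ExperimentStageError(DegensimError):
    """A stage of the experiment failed; the message names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"experiment stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one degeneration experiment."""

    generator: GeneratorConfig | None = None
    dataset_dir: str | None = None
    training: TrainingConfig = field(default_factory=TrainingConfig)
    n_replicates: int = 5
    schedule: inj.InjurySchedule = field(
        default_factory=lambda: inj.InjurySchedule(
            increment=0.005, max_fraction=0.5, rsa_checkpoints=DEFAULT_CHECKPOINTS
        )
    )
    injury_mode: str = "ablate-zero"
    base_seed: int = 0
    rsa_conditions_per_class: int = 10
    rsa_full_schedule: bool = False
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise InvalidArgumentError("n_replicates must be >= 1")
        if self.injury_mode not in inj.MODES:
            raise InvalidArgumentError(f"unknown injury mode {self.injury_mode!r}")
        if self.generator is None and self.dataset_dir is None:
            raise InvalidArgumentError("config needs a generator config or a dataset directory")
        if self.rsa_conditions_per_class < 2:
            raise InvalidArgumentError("rsa_conditions_per_class must be >= 2")


@dataclass(frozen=True)
class EvaluationRecord:
    """One row of the degeneration curve for one replicate."""

    replicate_id: int
    injured_fraction: float
    accuracy: float
    within_superclass_error_rate: float | None
    tau_a_object: float | None
    tau_a_superclass: float | None


@dataclass(frozen=True)
class SummaryRecord:
    """Mean/SD of one metric at one fraction across replicates."""

    injured_fraction: float
    metric: str
    mean: float
    sd: float
    n: int


def _rsa_subset(test: StimulusSet, per_class: int) -> np.ndarray:
    """Deterministic RSA condition set: first k test stimuli of each class."""
    idx = []
    for c in test.hierarchy.class_ids:
        members = np.flatnonzero(test.labels == c)[:per_class]
        if len(members) < 2:
            raise InvalidArgumentError(f"class {c} has < 2 test stimuli for RSA")
        idx.append(members)
    return np.concatenate(idx)


def run_experiment(
    cfg: ExperimentConfig,
) -> tuple[list[EvaluationRecord], list[SummaryRecord], dict]:
    """Run the full protocol; returns (records, summaries, artifacts).

    Artifacts: per-replicate uninjured reference RDMs, checkpoint RDMs,
    trained-baseline test accuracies, and the manifest dictionary.  When
    ``cfg.out_dir`` is set everything is also exported there; on a stage
    failure, partial outputs already written are kept and the manifest's
    ``incomplete`` flag remains true.
    """
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    manifest = _manifest(cfg)
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_manifest(manifest, out_dir)

    stage = "dataset"
    try:
        t0 = time.perf_counter()
        if cfg.dataset_dir is not None:
            (train, test), hierarchy = read_dataset(cfg.dataset_dir)
        else:
            gen_cfg = dataclasses.replace(cfg.generator, seed=cfg.base_seed)
            train, test = generate_dataset(gen_cfg)
            hierarchy = train.hierarchy
        logger.info("stage=dataset elapsed=%.2fs n_train=%d n_test=%d",
                    time.perf_counter() - t0, len(train), len(test))

        rsa_idx = _rsa_subset(test, cfg.rsa_conditions_per_class)
        rsa_set = StimulusSet(
            images=test.images[rsa_idx],
            labels=test.labels[rsa_idx],
            hierarchy=hierarchy,
            split_tag="test",
        )
        fractions = cfg.schedule.fractions()

        records: list[EvaluationRecord] = []
        artifacts: dict = {"reference_rdms": {}, "checkpoint_rdms": {}, "baseline_accuracy": {}}

        for r in range(cfg.n_replicates):
            stage = f"train[{r}]"
            t0 = time.perf_counter()
            seed_r = cfg.base_seed + 1 + r
            model = build_model(
                cfg.training.profile, hierarchy, seed_r,
                dropout_rate=cfg.training.dropout_rate,
                input_shape=train.images.shape[1:],
            )
            train_model(model, train, dataclasses.replace(cfg.training, seed=seed_r))
            base_batch = predict_labels(model, test)
            base_acc = accuracy(base_batch)
            artifacts["baseline_accuracy"][r] = base_acc
            logger.info("stage=train replicate=%d elapsed=%.2fs accuracy=%.4f",
                        r, time.perf_counter() - t0, base_acc)

            stage = f"reference-rdm[{r}]"
            ref_obj = build_rdm(penultimate_activations(model, rsa_set))
            ref_sup = superclass_rdm(ref_obj, rsa_set.labels, hierarchy)
            artifacts["reference_rdms"][r] = (ref_obj, ref_sup)

            stage = f"injury[{r}]"
            t0 = time.perf_counter()
            catalog = inj.build_catalog(model)
            unit_catalog = inj.build_unit_catalog(model) if cfg.injury_mode == "ablate-node" else None
            state = inj.initial_state(
                catalog, inj.injury_seed(cfg.base_seed, r), mode=cfg.injury_mode,
                unit_catalog=unit_catalog,
            )
            for f in fractions:
                state = inj.advance(state, float(f))
                injured = inj.apply(model, state)
                batch = predict_labels(injured, test)
                acc = accuracy(batch)
                wsc = within_superclass_error_rate(batch)
                tau_obj = tau_sup = None
                if cfg.rsa_full_schedule or cfg.schedule.is_checkpoint(float(f)):
                    rdm = build_rdm(penultimate_activations(injured, rsa_set))
                    srdm = superclass_rdm(rdm, rsa_set.labels, hierarchy)
                    tau_obj = compare_rdms(rdm, ref_obj).tau_a
                    # superclass comparison includes the within-superclass
                    # diagonal: with few superclasses the cross-block means
                    # are exchangeable and the within<between contrast is
                    # the robust part of the coarse geometry
                    tau_sup = compare_rdms(srdm, ref_sup, include_diagonal=True).tau_a
                    artifacts["checkpoint_rdms"][(r, float(f))] = rdm
                records.append(
                    EvaluationRecord(
                        replicate_id=r,
                        injured_fraction=float(f),
                        accuracy=acc,
                        within_superclass_error_rate=wsc,
                        tau_a_object=tau_obj,
                        tau_a_superclass=tau_sup,
                    )
                )
            logger.info("stage=injury replicate=%d elapsed=%.2fs steps=%d",
                        r, time.perf_counter() - t0, len(fractions))

        stage = "summarize"
        summaries = summarize(records)
    except DegensimError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-labeled with the failing stage
        raise ExperimentStageError(stage, exc) from exc

    manifest["incomplete"] = False
    artifacts["manifest"] = manifest
    if out_dir:
        export_results(records, summaries, out_dir, artifacts=artifacts, manifest=manifest)
    return records, summaries, artifacts


def summarize(records: list[EvaluationRecord]) -> list[SummaryRecord]:
    """Mean and sample SD (n-1 denominator) per metric per fraction.

    Undefined within-superclass values are excluded from that metric's n;
    a single contributing replicate reports SD = 0 with n = 1.
    """
    if not records:
        raise InvalidArgumentError("cannot summarize an empty record list")
    df = records_frame(records)
    out: list[SummaryRecord] = []
    metrics = ["accuracy", "within_superclass_error_rate", "tau_a_object", "tau_a_superclass"]
    for f, grp in df.groupby("injured_fraction", sort=True):
        for metric in metrics:
            vals = grp[metric].dropna()
            if len(vals) == 0:
                continue
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            out.append(
                SummaryRecord(
                    injured_fraction=float(f), metric=metric,
                    mean=float(vals.mean()), sd=sd, n=int(len(vals)),
                )
            )
    return out


def records_frame(records: list[EvaluationRecord]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(rec) for rec in records])
    return df[RECORDS_CSV_COLUMNS].astype({"replicate_id": int, "injured_fraction": float})


def summaries_frame(summaries: list[SummaryRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in summaries])


def _manifest(cfg: ExperimentConfig) -> dict:
    seeds = {
        "base_seed": cfg.base_seed,
        "generator_seed": cfg.base_seed if cfg.generator is not None else None,
        "training_seeds": [cfg.base_seed + 1 + r for r in range(cfg.n_replicates)],
        "injury_seeds": [inj.injury_seed(cfg.base_seed, r) for r in range(cfg.n_replicates)],
    }
    return {
        "format": "degensim-experiment",
        "version": 1,
        "config": _config_dict(cfg),
        "seeds": seeds,
        "incomplete": True,
    }


def _config_dict(cfg: ExperimentConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def _write_manifest(manifest: dict, directory: Path) -> None:
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def export_results(
    records: list[EvaluationRecord],
    summaries: list[SummaryRecord],
    directory: str | Path,
    artifacts: dict | None = None,
    manifest: dict | None = None,
) -> dict[str, Path]:
    """Write records/summaries CSVs, RDM container and manifest; idempotent.

    ``records.csv`` has exactly the documented column order; missing
    metrics are empty fields, never 0.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rec_path = directory / "records.csv"
    records_frame(records).to_csv(rec_path, index=False, na_rep="", float_format="%.17g")
    paths["records"] = rec_path

    sum_path = directory / "summaries.csv"
    summaries_frame(summaries).to_csv(sum_path, index=False, na_rep="", float_format="%.17g")
    paths["summaries"] = sum_path

    if artifacts:
        rdm_path = directory / "rdms.h5"
        with h5py.File(rdm_path, "w") as f:
            for r, (ref_obj, ref_sup) in artifacts.get("reference_rdms", {}).items():
                f.create_dataset(f"reference/replicate_{r}/object", data=ref_obj.matrix)
                f.create_dataset(f"reference/replicate_{r}/superclass", data=ref_sup.matrix)
            for (r, frac), rdm in artifacts.get("checkpoint_rdms", {}).items():
                f.create_dataset(f"checkpoint/replicate_{r}/f_{frac:.6f}", data=rdm.matrix)
        paths["rdms"] = rdm_path

    if manifest is not None:
        _write_manifest(manifest, directory)
        paths["manifest"] = directory / "manifest.json"
    return paths


def load_records(directory: str | Path) -> list[EvaluationRecord]:
    """Reload ``records.csv`` into EvaluationRecord rows (round-trip of export)."""
    df = pd.read_csv(Path(directory) / "records.csv", float_precision="round_trip")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            EvaluationRecord(
                replicate_id=int(row.replicate_id),
                injured_fraction=float(row.injured_fraction),
                accuracy=float(row.accuracy),
                within_superclass_error_rate=None
                if pd.isna(row.within_superclass_error_rate)
                else float(row.within_superclass_error_rate),
                tau_a_object=None if pd.isna(row.tau_a_object) else float(row.tau_a_object),
                tau_a_superclass=None
                if pd.isna(row.tau_a_superclass)
                else float(row.tau_a_superclass),
            )
        )
    return records
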