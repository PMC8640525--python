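"""Behavioral readouts: predictions, accuracy, chance levels, error structure.

The signature behavioral statistic is the *within-superclass error
rate*: among the stimuli a network misclassifies, the fraction whose
predicted class still falls in the true class's superclass (a rose
mistaken for a tulip rather than for a bicycle).  Networks never see
superclass labels, so any above-chance value reflects an emergent
hierarchical organisation of the learned classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import InvalidArgumentError
from .hierarchy import ClassHierarchy
from .nn import Network
from .synthetic_data import StimulusSet


@dataclass(frozen=True)
class PredictionBatch:
    """Predicted vs true class ids for one evaluation set."""

    predicted: np.ndarray
    true: np.ndarray
    hierarchy: ClassHierarchy

    def __post_init__(self) -> None:
        if len(self.predicted) != len(self.true):
            raise InvalidArgumentError("predicted and true labels must have equal length")
        valid = set(self.hierarchy.class_ids)
        for arr, which in ((self.predicted, "predicted"), (self.true, "true")):
            bad = set(np.unique(arr).tolist()) - valid
            if bad:
                raise InvalidArgumentError(f"{which} labels not in hierarchy: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.predicted)


def predict_labels(model: Network, stimuli: StimulusSet) -> PredictionBatch:
    """Arg-max class predictions; ties broken toward the lowest class id."""
    if model.n_classes != stimuli.hierarchy.n_classes:
        raise InvalidArgumentError(
            f"model outputs {model.n_classes} classes, dataset has "
            f"{stimuli.hierarchy.n_classes}"
        )
    probs = model.predict_proba(stimuli.images)
    predicted = np.argmax(probs, axis=1)  # first max = lowest class id on ties
    return PredictionBatch(predicted=predicted, true=np.asarray(stimuli.labels), hierarchy=stimuli.hierarchy)


def accuracy(batch: PredictionBatch) -> float:
    """Fraction of stimuli with predicted == true class."""
    if len(batch) == 0:
        raise InvalidArgumentError("cannot compute accuracy of an empty batch")
    return float(np.mean(batch.predicted == batch.true))


def chance_accuracy(label_counts: Mapping[int, int]) -> float:
    """Expected accuracy of a uniform random guesser over the label alphabet.

    sum_l (count_l / total) * (1/L); equals 1/L for balanced labels —
    1% for 100 classes, 5% for 20 superclasses.
    """
    if not label_counts:
        raise InvalidArgumentError("label_counts must be non-empty")
    total = sum(label_counts.values())
    if total <= 0:
        raise InvalidArgumentError("total label count must be positive")
    n_labels = len(label_counts)
    # sum_l (count_l/total) * (1/L) collapses to (1/L) * (sum_l count_l)/total;
    # computing it in this form keeps the result exact in floating point
    return (sum(label_counts.values()) / total) / n_labels


def superclass_chance(hierarchy: ClassHierarchy, convention: str = "marginal") -> float:
    """Chance level for the within-superclass error rate.

    ``marginal`` (default): probability of hitting the correct
    superclass out of S superclasses, i.e. 1/S — the convention used
    when quoting the 5% chance level for 20 superclasses.
    ``conditional``: exact expectation for a uniform class-level guesser
    restricted to *wrong* classes, (k-1)/(C-1) for a balanced hierarchy
    with k classes per superclass (4/99 ~ 4.04% at CIFAR-100 scale).
    """
    if convention == "marginal":
        return 1.0 / hierarchy.n_superclasses
    if convention == "conditional":
        c = hierarchy.n_classes
        same = [len(hierarchy.classes_in(s)) - 1 for s in hierarchy.superclass_ids]
        # average over true classes of (classes sharing its superclass - 1)/(C - 1)
        weights = [len(hierarchy.classes_in(s)) for s in hierarchy.superclass_ids]
        num = sum(w * k for w, k in zip(weights, same))
        return num / (c * (c - 1))
    raise InvalidArgumentError(f"unknown convention {convention!r}")


def within_superclass_error_rate(batch: PredictionBatch) -> float | None:
    """Among misclassified stimuli, fraction predicted in the correct superclass.

    Returns ``None`` (undefined) when the batch contains no errors; the
    statistic's denominator is the error set, and 0 or 1 would both be
    misleading for a perfect classifier.
    """
    sup = batch.hierarchy.superclass_of
    wrong = batch.predicted != batch.true
    n_wrong = int(wrong.sum())
    if n_wrong == 0:
        return None
    pred_sup = np.array([sup[int(c)] for c in batch.predicted[wrong]])
    true_sup = np.array([sup[int(c)] for c in batch.true[wrong]])
    return float(np.mean(pred_sup == true_sup))


def error_fraction(batch: PredictionBatch) -> float:
    """1 - accuracy; exposed for the accuracy/error partition identity."""
    return 1.0 - accuracy(batch)
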