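"""Two-level class/superclass label hierarchies.

The object-recognition datasets used here carry a two-level semantic
hierarchy: every fine-grained class (e.g. *rose*) belongs to exactly one
coarse superclass (e.g. *flowers*), mirroring CIFAR-100's 100 classes
nested in 20 superclasses.  Models are only ever trained on class labels;
the superclass structure exists purely for analysis (error structure,
superclass-level representational similarity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidArgumentError


@dataclass(frozen=True)
class ClassHierarchy:
    """Mapping of integer class ids 0..C-1 onto superclass ids 0..S-1.

    Parameters
    ----------
    class_ids
        Ordered tuple of class identifiers, always ``0..C-1``.
    superclass_of
        ``class_id -> superclass_id`` mapping covering every class id.
    """

    class_ids: tuple[int, ...]
    superclass_of: dict[int, int] = field(compare=True)

    def __post_init__(self) -> None:
        if len(self.class_ids) == 0:
            raise InvalidArgumentError("hierarchy must contain at least one class")
        missing = [c for c in self.class_ids if c not in self.superclass_of]
        if missing:
            raise InvalidArgumentError(f"classes without a superclass: {missing}")
        if self.n_superclasses < 2:
            raise InvalidArgumentError("hierarchy requires at least 2 superclasses")

    @property
    def n_classes(self) -> int:
        return len(self.class_ids)

    @property
    def superclass_ids(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.superclass_of[c] for c in self.class_ids)))

    @property
    def n_superclasses(self) -> int:
        return len(self.superclass_ids)

    def classes_in(self, superclass_id: int) -> tuple[int, ...]:
        """Class ids belonging to one superclass, in class-id order."""
        return tuple(c for c in self.class_ids if self.superclass_of[c] == superclass_id)


def make_hierarchy(n_superclasses: int, classes_per_superclass: int) -> ClassHierarchy:
    """Build a balanced hierarchy: class ``k`` maps to superclass ``k // classes_per_superclass``.

    With ``(20, 5)`` this reproduces the CIFAR-100 layout of 100 classes in
    20 balanced superclasses.
    """
    if n_superclasses < 2:
        raise InvalidArgumentError(f"n_superclasses must be >= 2, got {n_superclasses}")
    if classes_per_superclass < 1:
        raise InvalidArgumentError(
            f"classes_per_superclass must be >= 1, got {classes_per_superclass}"
        )
    n_classes = n_superclasses * classes_per_superclass
    class_ids = tuple(range(n_classes))
    superclass_of = {c: c // classes_per_superclass for c in class_ids}
    return ClassHierarchy(class_ids=class_ids, superclass_of=superclass_of)
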