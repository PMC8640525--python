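"""Representational similarity analysis over penultimate-layer activations.

An RDM (representational dissimilarity matrix) summarizes a network's
internal representation: entry (i, j) is ``1 - Pearson r`` between the
penultimate-layer activation patterns evoked by stimuli i and j.  The
course of representational degeneration is tracked by comparing each
injured network's RDM with the same network's uninjured RDM using
Kendall's tau_A — the rank correlation whose denominator counts *every*
unordered pair, with ties contributing zero to the numerator only (the
property that distinguishes tau_A from tau_B and makes it the standard
RDM-comparison statistic).

The noise floor — the tau_A expected when all representational
structure is gone — is estimated by comparing an RDM against a scrambled
copy of itself (uniform permutation of its upper-triangle entries).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import InvalidArgumentError
from .hierarchy import ClassHierarchy
from .nn import Network
from .synthetic_data import StimulusSet

logger = logging.getLogger(__name__)

#: auto-dispatch threshold: brute-force pair counting below this many pairs
BRUTE_FORCE_PAIR_LIMIT = 10_000


# -- Kendall tau_A -----------------------------------------------------


def kendall_tau_a_brute(v1: np.ndarray, v2: np.ndarray) -> float:
    """O(n^2) tau_A by explicit enumeration of all unordered pairs.

    Reference implementation; kept independent of the fast path so the
    two can be checked against each other.
    """
    v1, v2 = _check_pair(v1, v2)
    s1 = np.sign(np.subtract.outer(v1, v1))
    s2 = np.sign(np.subtract.outer(v2, v2))
    iu = np.triu_indices(len(v1), k=1)
    s = float(np.sum(s1[iu] * s2[iu]))
    return s / len(iu[0])


@njit
def _count_inversions(a: np.ndarray) -> int:
    """Strict inversions (i < j with a[i] > a[j]) via bottom-up merge sort."""
    n = a.size
    arr = a.copy()
    buf = np.empty(n, dtype=arr.dtype)
    inv = 0
    width = 1
    while width < n:
        lo = 0
        while lo < n:
            mid = min(lo + width, n)
            hi = min(lo + 2 * width, n)
            i, j, k = lo, mid, lo
            while i < mid and j < hi:
                if arr[j] < arr[i]:
                    inv += mid - i
                    buf[k] = arr[j]
                    j += 1
                else:
                    buf[k] = arr[i]
                    i += 1
                k += 1
            while i < mid:
                buf[k] = arr[i]
                i += 1
                k += 1
            while j < hi:
                buf[k] = arr[j]
                j += 1
                k += 1
            for t in range(lo, hi):
                arr[t] = buf[t]
            lo += 2 * width
        width *= 2
    return inv


def _tie_pairs(v: np.ndarray) -> int:
    _, counts = np.unique(v, return_counts=True)
    return int(np.sum(counts * (counts - 1) // 2))


def kendall_tau_a_fast(v1: np.ndarray, v2: np.ndarray) -> float:
    """O(n log n) tau_A: lexicographic sort + merge-sort inversion count.

    With pairs partitioned into concordant (C), discordant (D) and tied,
    ``C - D = n0 - tx - ty + txy - 2*D`` where tx/ty/txy count pairs tied
    in v1 / v2 / both; D is the number of strict y-inversions after
    sorting by (v1, v2).
    """
    v1, v2 = _check_pair(v1, v2)
    m = len(v1)
    n0 = m * (m - 1) // 2
    order = np.lexsort((v2, v1))
    ys = np.ascontiguousarray(v2[order])
    dis = _count_inversions(ys)
    tx = _tie_pairs(v1)
    ty = _tie_pairs(v2)
    pair_view = np.stack([v1, v2], axis=1)
    _, pair_counts = np.unique(pair_view, axis=0, return_counts=True)
    txy = int(np.sum(pair_counts * (pair_counts - 1) // 2))
    s = n0 - tx - ty + txy - 2 * dis
    return s / n0


def kendall_tau_a(v1: np.ndarray, v2: np.ndarray) -> float:
    """tau_A = (concordant - discordant) / (n(n-1)/2), ties in denominator."""
    v1c, _ = _check_pair(v1, v2)
    m = len(v1c)
    if m * (m - 1) // 2 < BRUTE_FORCE_PAIR_LIMIT:
        return kendall_tau_a_brute(v1, v2)
    return kendall_tau_a_fast(v1, v2)


def _check_pair(v1, v2) -> tuple[np.ndarray, np.ndarray]:
    v1 = np.asarray(v1, dtype=float).ravel()
    v2 = np.asarray(v2, dtype=float).ravel()
    if len(v1) != len(v2):
        raise InvalidArgumentError(f"length mismatch: {len(v1)} vs {len(v2)}")
    if len(v1) < 2:
        raise InvalidArgumentError("tau_A needs at least 2 entries")
    return v1, v2


# -- RDMs --------------------------------------------------------------


@dataclass(frozen=True)
class RDM:
    """Symmetric stimulus-pair dissimilarity matrix with condition ids.

    Stimulus-level RDMs have a zero diagonal; superclass-level RDMs
    carry the mean within-superclass dissimilarity on theirs (it is
    excluded from the comparison vector by construction).
    """

    condition_ids: tuple
    matrix: np.ndarray

    def __post_init__(self) -> None:
        d = self.matrix
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise InvalidArgumentError("RDM matrix must be square")
        if d.shape[0] != len(self.condition_ids):
            raise InvalidArgumentError("condition ids must match matrix size")
        if not np.allclose(d, d.T, atol=1e-9):
            raise InvalidArgumentError("RDM matrix must be symmetric")

    @property
    def n_conditions(self) -> int:
        return self.matrix.shape[0]


def penultimate_activations(model: Network, stimuli: StimulusSet) -> np.ndarray:
    """Post-activation outputs of the model's designated penultimate layer.

    Rows are stimuli (condition order = stimulus order), columns the
    layer's neurons; dropout is inactive, so the map is deterministic.
    """
    if not model.penultimate:
        raise InvalidArgumentError("model has no designated penultimate layer")
    return model.layer_activations(stimuli.images, model.penultimate)


def build_rdm(acts: np.ndarray, condition_ids=None) -> RDM:
    """``D[i, j] = 1 - Pearson r(row_i, row_j)`` over all stimulus pairs.

    Zero-variance activation rows (dead layers under heavy injury) have
    no defined correlation; their dissimilarity to every other row is
    set to 1 — the "uncorrelated" value — and the event is logged.
    """
    acts = np.asarray(acts, dtype=float)
    if acts.ndim != 2 or acts.shape[0] < 2:
        raise InvalidArgumentError("need a 2-D matrix with >= 2 stimulus rows")
    if acts.shape[1] < 2:
        raise InvalidArgumentError("Pearson correlation needs >= 2 neurons per row")
    n = acts.shape[0]
    centered = acts - acts.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    degenerate = norms == 0
    if degenerate.any():
        logger.warning(
            "RDM: %d zero-variance activation row(s); their dissimilarities set to 1",
            int(degenerate.sum()),
        )
    safe = np.where(degenerate, 1.0, norms)
    r = (centered @ centered.T) / np.outer(safe, safe)
    d = 1.0 - r
    d[degenerate, :] = 1.0
    d[:, degenerate] = 1.0
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    if condition_ids is None:
        condition_ids = tuple(range(n))
    return RDM(condition_ids=tuple(condition_ids), matrix=d)


def utv(rdm: RDM) -> np.ndarray:
    """Strict upper-triangle entries, row-major; length n(n-1)/2."""
    n = rdm.n_conditions
    return rdm.matrix[np.triu_indices(n, k=1)]


def from_utv(vector: np.ndarray, condition_ids=None) -> RDM:
    """Rebuild a symmetric zero-diagonal RDM from its upper-triangle vector."""
    vector = np.asarray(vector, dtype=float)
    n = int(round((1 + np.sqrt(1 + 8 * len(vector))) / 2))
    if n * (n - 1) // 2 != len(vector):
        raise InvalidArgumentError(f"vector length {len(vector)} is not n(n-1)/2")
    d = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    d[iu] = vector
    d = d + d.T
    return RDM(condition_ids=tuple(condition_ids) if condition_ids is not None else tuple(range(n)),
               matrix=d)


@dataclass(frozen=True)
class RDMComparison:
    """tau_A between two RDMs plus the number of compared entries."""

    tau_a: float
    n_pairs: int


def compare_rdms(a: RDM, b: RDM, include_diagonal: bool = False) -> RDMComparison:
    """tau_A of the two RDMs' upper-triangle vectors (same conditions required).

    ``include_diagonal=True`` compares the upper triangle *including* the
    diagonal.  For stimulus-level RDMs the diagonal is identically zero
    and must stay excluded; for superclass-level RDMs the diagonal holds
    the mean within-superclass dissimilarity, and including it makes the
    comparison sensitive to the within-vs-between organisation — the
    part of the coarse representational geometry that carries the
    hierarchy signal when the number of superclasses is small.
    """
    if a.condition_ids != b.condition_ids:
        raise InvalidArgumentError("RDMs must share identical condition ids and order")
    if include_diagonal:
        iu = np.triu_indices(a.n_conditions, k=0)
        va, vb = a.matrix[iu], b.matrix[iu]
    else:
        va, vb = utv(a), utv(b)
    return RDMComparison(tau_a=kendall_tau_a(va, vb), n_pairs=len(va))


@dataclass(frozen=True)
class NoiseFloorResult:
    """Scrambled-RDM comparison summary across repetitions."""

    mean_tau: float
    mean_abs_tau: float
    taus: tuple[float, ...]


def scrambled_noise_floor(
    rdm: RDM, n_reps: int, seed: int, method: str = "entries"
) -> NoiseFloorResult:
    """tau_A of an RDM against scrambled copies of itself.

    ``entries`` (default) permutes the upper-triangle entries uniformly,
    destroying all structure — a pure-noise reference.  ``rows`` applies
    one joint row/column permutation instead, preserving the entry
    multiset *and* the row structure.
    """
    if n_reps < 1:
        raise InvalidArgumentError("n_reps must be >= 1")
    if rdm.n_conditions < 3:
        raise InvalidArgumentError("noise floor needs >= 3 conditions (>= 2 pair entries)")
    rng = np.random.default_rng(seed)
    base = utv(rdm)
    taus = []
    for _ in range(n_reps):
        if method == "entries":
            scrambled = rng.permutation(base)
        elif method == "rows":
            perm = rng.permutation(rdm.n_conditions)
            scrambled = utv(RDM(rdm.condition_ids, rdm.matrix[np.ix_(perm, perm)]))
        else:
            raise InvalidArgumentError(f"unknown scramble method {method!r}")
        taus.append(kendall_tau_a(base, scrambled))
    taus_arr = np.array(taus)
    return NoiseFloorResult(
        mean_tau=float(taus_arr.mean()),
        mean_abs_tau=float(np.abs(taus_arr).mean()),
        taus=tuple(taus),
    )


def superclass_rdm(rdm: RDM, labels: np.ndarray, hierarchy: ClassHierarchy) -> RDM:
    """Block-average a stimulus-level RDM into an S x S superclass RDM.

    Off-diagonal (s, t): mean dissimilarity over all cross pairs; the
    diagonal keeps the mean over distinct within-superclass pairs (each
    superclass therefore needs >= 2 stimuli).
    """
    labels = np.asarray(labels)
    if len(labels) != rdm.n_conditions:
        raise InvalidArgumentError("need one class label per RDM condition")
    sup_lut = {c: hierarchy.superclass_of[c] for c in hierarchy.class_ids}
    sup = np.array([sup_lut[int(c)] for c in labels])
    sids = hierarchy.superclass_ids
    if len(sids) < 2:
        raise InvalidArgumentError("need >= 2 superclasses")
    s_count = len(sids)
    out = np.zeros((s_count, s_count))
    members = [np.flatnonzero(sup == s) for s in sids]
    for a in range(s_count):
        if len(members[a]) < 2:
            raise InvalidArgumentError(
                f"superclass {sids[a]} has {len(members[a])} stimuli; "
                "its within-superclass mean needs >= 2"
            )
        block = rdm.matrix[np.ix_(members[a], members[a])]
        k = len(members[a])
        out[a, a] = block.sum() / (k * (k - 1))  # diagonal of block is 0
        for b in range(a + 1, s_count):
            cross = rdm.matrix[np.ix_(members[a], members[b])]
            out[a, b] = out[b, a] = cross.mean()
    return RDM(condition_ids=tuple(sids), matrix=out)


def average_rdms(rdms: list[RDM]) -> RDM:
    """Elementwise mean of RDMs sharing condition ids (cross-replicate average)."""
    if not rdms:
        raise InvalidArgumentError("cannot average an empty list of RDMs")
    ref = rdms[0].condition_ids
    for r in rdms[1:]:
        if r.condition_ids != ref:
            raise InvalidArgumentError("all RDMs must share identical condition ids")
    stack = np.stack([r.matrix for r in rdms])
    return RDM(condition_ids=ref, matrix=stack.mean(axis=0))
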