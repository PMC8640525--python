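"""Cumulative random ablation of connection weights (simulated atrophy).

The core injury model mimics progressive synaptic loss: at each step a
random additional set of inter-neuron connection weights — convolutional
kernels and dense weight matrices, counted elementwise across every
layer including the output head — is set to exactly zero, and previously
injured connections stay at zero.  Biases are *not* ablatable: they are
per-neuron offsets, not connections between neurons.

Selection is one uniform draw over the global weight catalog (no
per-layer stratification) by default, matching an unstructured atrophy
process; a stratified per-layer mode supports layer-targeted injury.
Two variant injury modes from the same selection machinery:

``ablate-node``
    Units (dense neurons / conv channels) are the selection pool;
    ablating a unit zeroes all its incoming and outgoing weights,
    modeling neuronal rather than synaptic loss.  The injured fraction
    is interpreted over units.

``randomize``
    Selected weights are set to fresh zero-mean Gaussian draws scaled to
    the weight standard deviation of their layer, modeling synaptic
    dysregulation rather than loss.

Each replicate network owns an independent generator stream (derived
from the base seed by a counter rule), so every replicate's course of
degeneration is unique but exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError
from .nn import Network

MODES = ("ablate-zero", "ablate-node", "randomize")


# -- catalogs ----------------------------------------------------------


@dataclass(frozen=True)
class WeightCatalog:
    """Ordered global index over every ablatable scalar weight.

    Entry order is deterministic: layers in model order, elements
    row-major within each kernel tensor.  ``tensor_std`` records each
    tensor's weight standard deviation at catalog-build time (used by
    the randomize mode's replacement scale).
    """

    tensor_names: tuple[str, ...]
    tensor_sizes: tuple[int, ...]
    tensor_std: tuple[float, ...]

    @property
    def offsets(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum(self.tensor_sizes)])

    @property
    def total_count(self) -> int:
        return int(sum(self.tensor_sizes))

    def locate(self, global_index: int) -> tuple[str, int]:
        """Map a global index to ``(tensor_name, flat_position)``."""
        offs = self.offsets
        t = int(np.searchsorted(offs, global_index, side="right")) - 1
        if not 0 <= global_index < self.total_count:
            raise InvalidArgumentError(f"index {global_index} outside catalog [0, {self.total_count})")
        return self.tensor_names[t], int(global_index - offs[t])


def build_catalog(model: Network) -> WeightCatalog:
    """Catalog the model's connection weights (kernels only, biases excluded)."""
    names, sizes, stds = [], [], []
    for name, arr in model.get_weights().items():
        if name.endswith("/bias"):
            continue
        names.append(name)
        sizes.append(arr.size)
        stds.append(float(arr.std()))
    if not names:
        raise InvalidArgumentError("model exposes no connection-weight tensors")
    return WeightCatalog(tuple(names), tuple(sizes), tuple(stds))


@dataclass(frozen=True)
class UnitCatalog:
    """Selection pool for node ablation: one entry per hidden/output unit.

    ``unit_weights[u]`` lists ``(tensor_name, flat_indices)`` covering
    every weight incoming to or outgoing from unit ``u``.
    """

    unit_weights: tuple[tuple[tuple[str, np.ndarray], ...], ...]

    @property
    def total_count(self) -> int:
        return len(self.unit_weights)


def build_unit_catalog(model: Network) -> UnitCatalog:
    """Enumerate units (conv output channels, dense neurons) of every layer.

    The output layer's units are included: ablating one severs all its
    incoming connections.  Outgoing indices across a Flatten boundary
    account for the channel interleaving of the flattened feature map.
    """
    param_layers = [l for l in model.layers if l.params()]
    units: list[tuple[tuple[str, np.ndarray], ...]] = []
    for li, layer in enumerate(param_layers):
        kname = f"{layer.name}/kernel"
        k = layer.params()["kernel"]
        if k.ndim == 4:
            kh, kw, cin, cout = k.shape
            incoming = lambda u: u + cout * np.arange(kh * kw * cin)
        else:
            fin, fout = k.shape
            cout = fout
            incoming = lambda u: u + fout * np.arange(fin)
        nxt = param_layers[li + 1] if li + 1 < len(param_layers) else None
        for u in range(cout):
            touched = [(kname, incoming(u))]
            if nxt is not None:
                nk = nxt.params()["kernel"]
                nkname = f"{nxt.name}/kernel"
                if nk.ndim == 4:  # conv -> conv
                    nkh, nkw, ncin, ncout = nk.shape
                    base = (np.arange(nkh * nkw) * ncin + u) * ncout
                    out_idx = (base[:, None] + np.arange(ncout)[None, :]).ravel()
                else:  # (conv -> flatten ->) dense or dense -> dense
                    fin, fout = nk.shape
                    if fin == cout:  # dense -> dense
                        rows = np.array([u])
                    else:  # flattened conv map: every spatial position of channel u
                        if fin % cout:
                            raise InvalidArgumentError(
                                f"cannot map units of {layer.name} onto {nxt.name} inputs"
                            )
                        rows = u + cout * np.arange(fin // cout)
                    out_idx = (rows[:, None] * fout + np.arange(fout)[None, :]).ravel()
                touched.append((nkname, out_idx))
            units.append(tuple(touched))
    return UnitCatalog(tuple(units))


# -- schedule and counts -----------------------------------------------


def target_count(fraction: float, n: int) -> int:
    """Number of injured elements at a nominal fraction.

    Nearest-integer rounding, halves away from zero, so a cumulative
    fine-grained schedule and a single direct jump reach identical
    counts at every shared fraction.
    """
    if not 0.0 <= fraction <= 1.0:
        raise InvalidArgumentError(f"fraction must be in [0, 1], got {fraction}")
    return int(math.floor(fraction * n + 0.5))


@dataclass(frozen=True)
class InjurySchedule:
    """Injury course: fraction step, endpoint, and RSA checkpoint fractions."""

    increment: float = 0.001
    max_fraction: float = 0.5
    rsa_checkpoints: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        ok = 0.0 < self.increment <= 1.0 and 0.0 <= self.max_fraction <= 1.0
        # max_fraction 0 means "baseline only"; otherwise increment must fit
        if ok and self.max_fraction > 0.0:
            ok = self.increment <= self.max_fraction
        if not ok:
            raise InvalidArgumentError(
                f"need 0 < increment <= max_fraction <= 1 (or max_fraction 0), got "
                f"({self.increment}, {self.max_fraction})"
            )
        achievable = self.fractions()
        for cp in self.rsa_checkpoints:
            if not np.any(np.isclose(achievable, cp, atol=1e-12)):
                raise InvalidArgumentError(f"checkpoint {cp} not on the schedule grid")

    def fractions(self) -> np.ndarray:
        """All visited fractions including 0, on an exact grid."""
        n_steps = int(round(self.max_fraction / self.increment))
        return np.round(np.arange(n_steps + 1) * self.increment, 12)

    def is_checkpoint(self, f: float) -> bool:
        return bool(np.any(np.isclose(self.rsa_checkpoints, f, atol=1e-12)))


# -- injury state ------------------------------------------------------


def injury_seed(base_seed: int, replicate_index: int) -> int:
    """Counter rule deriving each replicate's injury stream seed."""
    return int(base_seed) + 100_000 + int(replicate_index)


@dataclass
class InjuryState:
    """Cumulative injury of one network: which pool entries are injured.

    For weight modes the pool is the weight catalog; for ``ablate-node``
    it is the unit catalog.  States form a linear chain — each
    :func:`advance` consumes the shared generator stream, so the course
    of degeneration is unique per seed and checkpoints do not perturb
    which entries get injured at a given fraction.
    """

    catalog: WeightCatalog
    mask: np.ndarray  # bool, over the selection pool
    fraction: float
    mode: str
    rng: np.random.Generator
    unit_catalog: UnitCatalog | None = None
    replacements: dict[int, float] = field(default_factory=dict)
    stratified: bool = False

    @property
    def injured(self) -> np.ndarray:
        """Sorted pool indices currently injured."""
        return np.flatnonzero(self.mask)

    @property
    def pool_size(self) -> int:
        return self.mask.size


def initial_state(
    catalog: WeightCatalog,
    seed: int,
    mode: str = "ablate-zero",
    unit_catalog: UnitCatalog | None = None,
    stratified: bool = False,
) -> InjuryState:
    if mode not in MODES:
        raise InvalidArgumentError(f"unknown injury mode {mode!r}; choose from {MODES}")
    if mode == "ablate-node":
        if unit_catalog is None:
            raise InvalidArgumentError("ablate-node mode requires a unit catalog")
        pool = unit_catalog.total_count
    else:
        pool = catalog.total_count
    return InjuryState(
        catalog=catalog,
        mask=np.zeros(pool, dtype=bool),
        fraction=0.0,
        mode=mode,
        rng=np.random.default_rng(seed),
        unit_catalog=unit_catalog,
        stratified=stratified,
    )


def advance(state: InjuryState, new_fraction: float, catalog: WeightCatalog | None = None) -> InjuryState:
    """Extend the injury to ``new_fraction``; irreversible and cumulative.

    Selects exactly ``target_count(new_f) - target_count(old_f)`` fresh
    entries uniformly without replacement from the uninjured pool.
    """
    if catalog is not None and catalog is not state.catalog and catalog != state.catalog:
        raise InvalidArgumentError("catalog does not match the one bound to this state")
    if not 0.0 <= new_fraction <= 1.0:
        raise InvalidArgumentError(f"fraction must be in [0, 1], got {new_fraction}")
    if new_fraction < state.fraction - 1e-12:
        raise InvalidArgumentError(
            f"injury is irreversible: cannot go from {state.fraction} to {new_fraction}"
        )
    mask = state.mask.copy()
    replacements = dict(state.replacements)
    if state.stratified and state.mode != "ablate-node":
        offs = state.catalog.offsets
        for t, size in enumerate(state.catalog.tensor_sizes):
            seg = slice(int(offs[t]), int(offs[t]) + size)
            have = int(mask[seg].sum())
            want = target_count(new_fraction, size)
            k = want - have
            if k > 0:
                free = np.flatnonzero(~mask[seg]) + offs[t]
                picked = state.rng.choice(free, size=k, replace=False)
                mask[picked] = True
                _record_replacements(state, picked, replacements)
    else:
        want = target_count(new_fraction, mask.size)
        k = want - int(mask.sum())
        if k > 0:
            free = np.flatnonzero(~mask)
            picked = state.rng.choice(free, size=k, replace=False)
            mask[picked] = True
            _record_replacements(state, picked, replacements)
    return InjuryState(
        catalog=state.catalog,
        mask=mask,
        fraction=float(new_fraction),
        mode=state.mode,
        rng=state.rng,
        unit_catalog=state.unit_catalog,
        replacements=replacements,
        stratified=state.stratified,
    )


def _record_replacements(state: InjuryState, picked: np.ndarray, replacements: dict[int, float]) -> None:
    if state.mode != "randomize":
        return
    offs = state.catalog.offsets
    for gi in np.sort(picked):
        t = int(np.searchsorted(offs, gi, side="right")) - 1
        replacements[int(gi)] = float(state.rng.normal(0.0, state.catalog.tensor_std[t]))


def advance_variant(
    state: InjuryState, new_fraction: float, catalog: WeightCatalog | None, mode: str
) -> InjuryState:
    """Variant-mode advance; the state must already carry the given mode."""
    if mode not in MODES:
        raise InvalidArgumentError(f"unknown injury mode {mode!r}; choose from {MODES}")
    if state.mode != mode:
        raise InvalidArgumentError(f"state has mode {state.mode!r}, requested {mode!r}")
    return advance(state, new_fraction, catalog)


def apply(model: Network, state: InjuryState) -> Network:
    """Return an injured copy of ``model``; the original is untouched.

    ablate-zero: injured weights set to exactly 0.  randomize: injured
    weights set to their recorded replacement draws.  ablate-node: all
    weights touching an injured unit set to 0.  Uninjured weights and
    all biases are bit-identical to the input model.
    """
    weights = model.get_weights()
    for name, size in zip(state.catalog.tensor_names, state.catalog.tensor_sizes):
        if name not in weights or weights[name].size != size:
            raise InvalidArgumentError(
                f"catalog/model mismatch: tensor {name!r} missing or resized"
            )
    injured_model = model.copy()
    if state.mode == "ablate-node":
        flat_by_tensor: dict[str, list[np.ndarray]] = {}
        for u in state.injured:
            for tname, idx in state.unit_catalog.unit_weights[u]:
                flat_by_tensor.setdefault(tname, []).append(idx)
        for tname, idx_lists in flat_by_tensor.items():
            arr = injured_model.get_weights()[tname].copy()
            flat = arr.reshape(-1)
            flat[np.concatenate(idx_lists)] = 0.0
            injured_model.set_weight(tname, arr)
        return injured_model

    offs = state.catalog.offsets
    injured = state.injured
    for t, (tname, size) in enumerate(zip(state.catalog.tensor_names, state.catalog.tensor_sizes)):
        lo, hi = int(offs[t]), int(offs[t]) + size
        sel = injured[(injured >= lo) & (injured < hi)]
        if sel.size == 0:
            continue
        arr = injured_model.get_weights()[tname].copy()
        flat = arr.reshape(-1)
        local = sel - lo
        if state.mode == "randomize":
            flat[local] = [state.replacements[int(g)] for g in sel]
        else:
            flat[local] = 0.0
        injured_model.set_weight(tname, arr)
    return injured_model
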