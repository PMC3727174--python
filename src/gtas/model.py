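"""GTaS model definition and elementary derived quantities.

A GTaS (generalized thinning and shift) process is parameterized by

* a mother-process rate ``lambda`` (homogeneous Poisson on the line),
* a sparse marking distribution ``p_D`` over nonempty subsets
  ``D`` of the train set ``{1..N}``, and
* a shift distribution ``Q_D`` for every marking with positive probability.

Each mother event is marked with a subset ``D`` (probability ``p_D``), a
shift vector ``Y ~ Q_D`` is drawn, and train ``i in D`` receives the event at
``t + Y_i``.  Every train is marginally Poisson; the markings and shifts set
the joint cumulant structure at all orders.

Subsets are handled sparsely as canonical sorted 1-based tuples; the power
set is never materialized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

import numpy as np

from .shifts import Mixture1D, ShiftDistribution

SubsetKey = Tuple[int, ...]

#: silent-renormalization threshold for the marking probabilities
NORMALIZATION_TOL = 1e-9


class ModelValidationError(ValueError):
    """A GTaS parameter bundle violates a model invariant."""


def canonical_subset(subset, n_trains: int) -> SubsetKey:
    """Canonicalize a subset of ``{1..N}`` as a sorted tuple.

    Raises on duplicates, out-of-range indices, or the empty set (empty
    markings are disallowed; express deletion by lowering the mother rate).
    """
    try:
        key = tuple(sorted(int(i) for i in subset))
    except TypeError as exc:
        raise ModelValidationError(f"subset {subset!r} is not an index collection") from exc
    if len(key) == 0:
        raise ModelValidationError("empty marking subsets are not allowed")
    if len(set(key)) != len(key):
        raise ModelValidationError(f"duplicate index in subset {subset!r}")
    if key[0] < 1 or key[-1] > n_trains:
        raise ModelValidationError(f"subset {subset!r} not contained in 1..{n_trains}")
    return key


def subset_to_bitmask(subset: SubsetKey) -> int:
    mask = 0
    for i in subset:
        mask |= 1 << (i - 1)
    return mask


def bitmask_to_subset(mask: int) -> SubsetKey:
    return tuple(i + 1 for i in range(mask.bit_length()) if mask >> i & 1)


@dataclass(frozen=True)
class GTaSModel:
    """A validated GTaS parameterization.

    Construct through :func:`validate_model` (or the ``model`` classmethod of
    the special-model builders) rather than directly; ``validate_model``
    canonicalizes keys and enforces the invariants.
    """

    n_trains: int
    mother_rate: float
    markings: Mapping[SubsetKey, float]
    shifts: Mapping[SubsetKey, ShiftDistribution]

    @property
    def full_set(self) -> SubsetKey:
        return tuple(range(1, self.n_trains + 1))

    def support_bound(self, mass_tol: float = 1e-9) -> float:
        """Smallest ``b`` reported by the shift families such that
        ``P(|Y_i| > b) < mass_tol`` under every marking's shift law."""
        return max(d.abs_bound(mass_tol) for d in self.shifts.values())

    def __eq__(self, other):
        if not isinstance(other, GTaSModel):
            return NotImplemented
        return (
            self.n_trains == other.n_trains
            and self.mother_rate == other.mother_rate
            and dict(self.markings) == dict(other.markings)
            and dict(self.shifts) == dict(other.shifts)
        )


def validate_model(
    n_trains: int,
    mother_rate: float,
    markings: Mapping,
    shifts: Mapping,
) -> GTaSModel:
    """Canonicalize and validate a raw GTaS parameter bundle.

    Probabilities are silently renormalized when ``|sum - 1| <``
    :data:`NORMALIZATION_TOL` (absorbing config round-off); larger deviations
    raise :class:`ModelValidationError`.
    """
    n_trains = int(n_trains)
    if n_trains < 1:
        raise ModelValidationError("n_trains must be >= 1")
    mother_rate = float(mother_rate)
    if not mother_rate > 0:
        raise ModelValidationError("mother rate must be positive")

    canon_markings: Dict[SubsetKey, float] = {}
    for subset, prob in markings.items():
        key = canonical_subset(subset, n_trains)
        prob = float(prob)
        if prob < 0:
            raise ModelValidationError(f"negative probability for marking {key}")
        if prob == 0.0:
            continue
        if key in canon_markings:
            raise ModelValidationError(f"marking {key} listed twice")
        canon_markings[key] = prob
    if not canon_markings:
        raise ModelValidationError("at least one marking with positive probability is required")

    total = sum(canon_markings.values())
    if abs(total - 1.0) > NORMALIZATION_TOL:
        raise ModelValidationError(f"markings not normalized: sum = {total!r}")
    if abs(total - 1.0) > 1e-15:
        # renormalize config round-off; deviations at machine precision are
        # kept as-is so that save -> load round-trips bit-exactly
        canon_markings = {k: v / total for k, v in canon_markings.items()}

    canon_shifts: Dict[SubsetKey, ShiftDistribution] = {}
    for subset, dist in shifts.items():
        key = canonical_subset(subset, n_trains)
        if not isinstance(dist, ShiftDistribution):
            raise ModelValidationError(f"shift for marking {key} is not a ShiftDistribution")
        if dist.dim != n_trains:
            raise ModelValidationError(
                f"shift for marking {key} has dimension {dist.dim}, expected {n_trains}"
            )
        canon_shifts[key] = dist
    for key in canon_markings:
        if key not in canon_shifts:
            raise ModelValidationError(f"marking {key} has no shift distribution")
    canon_shifts = {k: canon_shifts[k] for k in canon_markings}

    return GTaSModel(
        n_trains=n_trains,
        mother_rate=mother_rate,
        markings=canon_markings,
        shifts=canon_shifts,
    )


def tail_probability(model: GTaSModel, subset) -> float:
    """Tail probability ``pbar_D``: total marking mass on supersets of ``D``.

    This is the probability that every train in ``D`` (and possibly others)
    receives a copy of a given mother event.
    """
    key = canonical_subset(subset, model.n_trains)
    target = set(key)
    return float(
        sum(p for d, p in model.markings.items() if target.issubset(d))
    )


def marginal_rate(model: GTaSModel, i: int) -> float:
    """Rate of daughter train ``i``: ``lambda * pbar_{i}`` (IID shifting of a
    Poisson process leaves it Poisson with the same rate)."""
    if not 1 <= int(i) <= model.n_trains:
        raise ModelValidationError(f"train index {i} out of range 1..{model.n_trains}")
    return model.mother_rate * tail_probability(model, (int(i),))


def marginal_mixture_shift(model: GTaSModel, i: int):
    """The mixture law of the shift applied to events of train ``i``:
    ``sum_{D ∋ i} p_D Q_D^{i} / pbar_{i}``.

    Returns the lone component unchanged when only one marking contains
    ``i``; otherwise a :class:`~gtas.shifts.Mixture1D`.
    """
    i = int(i)
    if not 1 <= i <= model.n_trains:
        raise ModelValidationError(f"train index {i} out of range 1..{model.n_trains}")
    weights, comps = [], []
    for d, p in model.markings.items():
        if i in d:
            weights.append(p)
            comps.append(model.shifts[d].marginal1d(i))
    if not comps:
        raise ModelValidationError(f"train {i} is never marked (pbar = 0)")
    if len(comps) == 1:
        return comps[0]
    w = np.asarray(weights) / np.sum(weights)
    return Mixture1D(w, comps)
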