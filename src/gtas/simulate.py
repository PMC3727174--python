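"""Sampling GTaS realizations.

Two distributionally identical samplers are provided:

* :func:`simulate_thinning` — the defining three-step algorithm: one mother
  Poisson process, per-event marking, per-event shift vector.
* :func:`simulate_superposition` — one independent Poisson component per
  marking with rate ``lambda * p_D``, shifted and merged.  Useful as a
  cross-check of the thinning sampler.

Edge handling: the mother process is drawn on a padded interval wide enough
that shifted events falling inside the observation window are captured up to
a shift-mass tolerance; shifted events landing outside the window are
dropped.  Event times are continuous (no grid).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .model import GTaSModel, subset_to_bitmask


@dataclass
class SpikeTrainSet:
    """``n_trains`` sorted event-time sequences on ``[t_start, t_stop)``.

    ``marking`` / ``mother_id`` are optional per-train provenance arrays
    aligned with ``trains`` (marking as a bitmask over train indices).
    """

    n_trains: int
    t_start: float
    t_stop: float
    trains: List[np.ndarray]
    marking: Optional[List[np.ndarray]] = None
    mother_id: Optional[List[np.ndarray]] = None

    def __post_init__(self):
        if len(self.trains) != self.n_trains:
            raise ValueError("one event array per train is required")
        if not self.t_stop > self.t_start:
            raise ValueError("empty observation window")
        for t in self.trains:
            if t.size and (t.min() < self.t_start or t.max() >= self.t_stop):
                raise ValueError("event time outside the observation window")
            if np.any(np.diff(t) < 0):
                raise ValueError("train event times must be sorted")

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    def counts(self) -> np.ndarray:
        return np.array([t.size for t in self.trains])

    def rates(self) -> np.ndarray:
        return self.counts() / self.duration


def pad_and_crop(window, shift_support_bound: float):
    """Padded mother-process interval ``[t0 - b, t1 + b]`` for a shift-support
    bound ``b`` (a quantile bound on ``|Y|`` mass)."""
    t0, t1 = float(window[0]), float(window[1])
    if not t1 > t0:
        raise ValueError("window must be nonempty")
    b = float(shift_support_bound)
    if b < 0:
        raise ValueError("shift support bound must be nonnegative")
    return (t0 - b, t1 + b)


def _mother_events(rate: float, padded, rng: np.random.Generator) -> np.ndarray:
    t0, t1 = padded
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def _empty_result(model, window, provenance):
    trains = [np.empty(0) for _ in range(model.n_trains)]
    marks = [np.empty(0, dtype=np.int64) for _ in range(model.n_trains)] if provenance else None
    moms = [np.empty(0, dtype=np.int64) for _ in range(model.n_trains)] if provenance else None
    return trains, marks, moms


def _scatter(model, times, marking_idx, shift_rows, window, provenance, mother_offset=0):
    """Distribute shifted copies of mother events onto daughter trains.

    ``shift_rows[j]`` is the shift vector for mother event ``j``.
    """
    t0, t1 = float(window[0]), float(window[1])
    keys = list(model.markings)
    per_train = [[] for _ in range(model.n_trains)]
    per_mark = [[] for _ in range(model.n_trains)] if provenance else None
    per_mom = [[] for _ in range(model.n_trains)] if provenance else None
    for mi, key in enumerate(keys):
        sel = np.flatnonzero(marking_idx == mi)
        if sel.size == 0:
            continue
        mask = subset_to_bitmask(key)
        for i in key:
            shifted = times[sel] + shift_rows[sel, i - 1]
            keep = (shifted >= t0) & (shifted < t1)
            per_train[i - 1].append(shifted[keep])
            if provenance:
                per_mark[i - 1].append(np.full(int(keep.sum()), mask, dtype=np.int64))
                per_mom[i - 1].append((sel[keep] + mother_offset).astype(np.int64))
    trains, marks, moms = [], [], []
    for i in range(model.n_trains):
        t = np.concatenate(per_train[i]) if per_train[i] else np.empty(0)
        order = np.argsort(t, kind="stable")
        trains.append(t[order])
        if provenance:
            marks.append(np.concatenate(per_mark[i])[order] if per_mark[i] else np.empty(0, np.int64))
            moms.append(np.concatenate(per_mom[i])[order] if per_mom[i] else np.empty(0, np.int64))
    return trains, (marks if provenance else None), (moms if provenance else None)


def _draw_shifts(model, marking_idx, rng, override=None):
    """One shift vector per mother event, drawn marking-by-marking in
    canonical key order (fixed RNG consumption order for reproducibility)."""
    keys = list(model.markings)
    rows = np.zeros((marking_idx.size, model.n_trains))
    for mi, key in enumerate(keys):
        sel = np.flatnonzero(marking_idx == mi)
        if sel.size == 0:
            continue
        dist = model.shifts[key] if override is None else override.get(key, model.shifts[key])
        rows[sel] = dist.sample(sel.size, rng)
    return rows


def simulate_thinning(
    model: GTaSModel,
    window,
    rng: np.random.Generator,
    provenance: bool = False,
    mass_tol: float = 1e-9,
) -> SpikeTrainSet:
    """Sample by the defining algorithm: mother process, markings, shifts."""
    padded = pad_and_crop(window, model.support_bound(mass_tol))
    times = _mother_events(model.mother_rate, padded, rng)
    probs = np.array(list(model.markings.values()))
    if times.size:
        marking_idx = rng.choice(len(probs), size=times.size, p=probs)
        shift_rows = _draw_shifts(model, marking_idx, rng)
        trains, marks, moms = _scatter(model, times, marking_idx, shift_rows, window, provenance)
    else:
        trains, marks, moms = _empty_result(model, window, provenance)
    return SpikeTrainSet(model.n_trains, float(window[0]), float(window[1]),
                         trains, marking=marks, mother_id=moms)


def simulate_superposition(
    model: GTaSModel,
    window,
    rng: np.random.Generator,
    provenance: bool = False,
    mass_tol: float = 1e-9,
) -> SpikeTrainSet:
    """Sample as a superposition of independent per-marking Poisson
    components with rates ``lambda * p_D`` — equal in law to thinning."""
    padded = pad_and_crop(window, model.support_bound(mass_tol))
    all_times, all_idx = [], []
    for mi, (key, p) in enumerate(model.markings.items()):
        t = _mother_events(model.mother_rate * p, padded, rng)
        all_times.append(t)
        all_idx.append(np.full(t.size, mi))
    times = np.concatenate(all_times) if all_times else np.empty(0)
    marking_idx = np.concatenate(all_idx) if all_idx else np.empty(0, int)
    if times.size:
        shift_rows = _draw_shifts(model, marking_idx, rng)
        trains, marks, moms = _scatter(model, times, marking_idx, shift_rows, window, provenance)
    else:
        trains, marks, moms = _empty_result(model, window, provenance)
    return SpikeTrainSet(model.n_trains, float(window[0]), float(window[1]),
                         trains, marking=marks, mother_id=moms)


def simulate_matched(
    models: Sequence[GTaSModel],
    window,
    rng: np.random.Generator,
    provenance: bool = False,
    mass_tol: float = 1e-9,
) -> List[SpikeTrainSet]:
    """Common-random-numbers sampling for models that share ``lambda`` and
    ``p_D``: one mother realization and one marking assignment per call, with
    shift draws shared wherever the models' ``Q_D`` agree and drawn from
    independent per-model streams where they differ.

    This is the paired-trial design of the cascade-amplification experiment.
    """
    base = models[0]
    for m in models[1:]:
        if m.n_trains != base.n_trains or m.mother_rate != base.mother_rate:
            raise ValueError("matched models must share the mother rate and size")
        if dict(m.markings) != dict(base.markings):
            raise ValueError("matched models must share the marking distribution")
    bound = max(m.support_bound(mass_tol) for m in models)
    padded = pad_and_crop(window, bound)
    times = _mother_events(base.mother_rate, padded, rng)
    probs = np.array(list(base.markings.values()))
    if times.size == 0:
        out = []
        for m in models:
            trains, marks, moms = _empty_result(m, window, provenance)
            out.append(SpikeTrainSet(m.n_trains, float(window[0]), float(window[1]),
                                     trains, marking=marks, mother_id=moms))
        return out
    marking_idx = rng.choice(len(probs), size=times.size, p=probs)
    shared = {
        key: all(m.shifts[key] == base.shifts[key] for m in models[1:])
        for key in base.markings
    }
    common_rows = _draw_shifts(base, marking_idx, rng,
                               override={k: base.shifts[k] for k in base.markings})
    streams = rng.spawn(len(models))
    out = []
    for m, sub_rng in zip(models, streams):
        rows = common_rows.copy()
        keys = list(base.markings)
        for mi, key in enumerate(keys):
            if shared[key]:
                continue
            sel = np.flatnonzero(marking_idx == mi)
            if sel.size:
                rows[sel] = m.shifts[key].sample(sel.size, sub_rng)
        trains, marks, moms = _scatter(m, times, marking_idx, rows, window, provenance)
        out.append(SpikeTrainSet(m.n_trains, float(window[0]), float(window[1]),
                                 trains, marking=marks, mother_id=moms))
    return out
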