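"""Plug-in cumulant estimation from spike-train data.

The joint cumulant of ``k`` variables is computed from the partition
formula

    kappa(X_1..X_k) = sum_pi (|pi|-1)! (-1)^(|pi|-1)
                          prod_{B in pi} E[ prod_{i in B} X_i ]

with sample means substituted for the expectations (a consistent, mildly
biased plug-in; bias is O(1/n)).  Cumulant *densities* are estimated by
binning each train, forming lagged count vectors and dividing the binned
joint cumulant by ``dt^k``.  Standard errors come from a block bootstrap
over bins (blocks absorb the short-range dependence left by the shifts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .analytic import CumulantDensity
from .simulate import SpikeTrainSet

#: partition enumeration guard (Bell(6) = 203 partitions)
MAX_ORDER = 6


class EstimationError(ValueError):
    """An estimate was requested from insufficient data."""


@dataclass
class BinnedCounts:
    """Per-train spike counts in half-open bins of width ``dt``."""

    dt: float
    t_start: float
    counts: np.ndarray  # (n_trains, n_bins)

    @property
    def n_trains(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


def bin_counts(spikes: SpikeTrainSet, dt: float) -> BinnedCounts:
    """Discretize to bins ``[t_start + m*dt, t_start + (m+1)*dt)``; a
    trailing partial bin is dropped.  Events exactly on an interior edge go
    to the right bin."""
    dt = float(dt)
    if dt <= 0:
        raise EstimationError("bin width must be positive")
    n_bins = int(np.floor(spikes.duration / dt))
    if n_bins < 1:
        raise EstimationError("window shorter than one bin")
    counts = np.zeros((spikes.n_trains, n_bins), dtype=np.int64)
    for i, t in enumerate(spikes.trains):
        b = np.floor((t - spikes.t_start) / dt).astype(np.int64)
        b = b[(b >= 0) & (b < n_bins)]
        counts[i] = np.bincount(b, minlength=n_bins)
    return BinnedCounts(dt=dt, t_start=spikes.t_start, counts=counts)


# ---------------------------------------------------------------------------
# Partition formula
# ---------------------------------------------------------------------------

def _gen_partitions(items):
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in _gen_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


@lru_cache(maxsize=None)
def set_partitions(k: int) -> Tuple[Tuple[Tuple[int, ...], ...], ...]:
    """All partitions of ``{0..k-1}`` as tuples of blocks."""
    return tuple(
        tuple(tuple(b) for b in part) for part in _gen_partitions(list(range(k)))
    )


def _cumulant_from_moments(moments: Dict[frozenset, np.ndarray], k: int):
    total = None
    for part in set_partitions(k):
        prod = None
        for block in part:
            m = moments[frozenset(block)]
            prod = m if prod is None else prod * m
        term = (-1) ** (len(part) - 1) * math.factorial(len(part) - 1) * prod
        total = term if total is None else total + term
    return total


def joint_cumulant(samples: np.ndarray) -> float:
    """Plug-in joint cumulant of the columns of an ``(n_obs, k)`` sample
    matrix (columns may repeat for auto-cumulants)."""
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2:
        raise EstimationError("samples must be an (n_obs, k) matrix")
    n, k = x.shape
    if n < 2:
        raise EstimationError("at least two observations are required")
    if not 1 <= k <= MAX_ORDER:
        raise EstimationError(f"order must be in 1..{MAX_ORDER} (partition guard)")
    moments = {}
    for subset in _monomial_subsets(k):
        moments[frozenset(subset)] = float(np.prod(x[:, list(subset)], axis=1).mean())
    return float(_cumulant_from_moments(moments, k))


@lru_cache(maxsize=None)
def _monomial_subsets(k: int) -> Tuple[Tuple[int, ...], ...]:
    subs = []
    for mask in range(1, 1 << k):
        subs.append(tuple(i for i in range(k) if mask >> i & 1))
    return tuple(subs)


# ---------------------------------------------------------------------------
# Block bootstrap plumbing
# ---------------------------------------------------------------------------

class _WeightCache:
    """Bootstrap block-count matrices, one per distinct block count, so that
    every quantity estimated in one call shares the same resamples."""

    def __init__(self, n_boot: int, rng: np.random.Generator):
        self.n_boot = n_boot
        self.rng = rng
        self._cache: Dict[int, np.ndarray] = {}

    def get(self, n_blocks: int) -> np.ndarray:
        if n_blocks not in self._cache:
            idx = self.rng.integers(0, n_blocks, size=(self.n_boot, n_blocks))
            w = np.zeros((self.n_boot, n_blocks))
            for r in range(self.n_boot):
                w[r] = np.bincount(idx[r], minlength=n_blocks)
            self._cache[n_blocks] = w
        return self._cache[n_blocks]


def _plugin_with_reps(cols: List[np.ndarray], weights: Optional[_WeightCache],
                      block_len: int):
    """Plug-in cumulant of aligned observation columns, plus bootstrap
    replicates built from per-block sums of every monomial."""
    k = len(cols)
    m_full = cols[0].size
    n_blocks = m_full // block_len
    if n_blocks < 2:
        raise EstimationError("too few observations for the block bootstrap")
    m = n_blocks * block_len
    subsets = _monomial_subsets(k)
    mono = np.empty((len(subsets), m))
    fcols = [np.asarray(c[:m], dtype=float) for c in cols]
    for si, s in enumerate(subsets):
        prod = fcols[s[0]].copy()
        for j in s[1:]:
            prod *= fcols[j]
        mono[si] = prod
    means = mono.mean(axis=1)
    est = _cumulant_from_moments(
        {frozenset(s): means[si] for si, s in enumerate(subsets)}, k
    )
    if weights is None:
        return float(est), None
    w = weights.get(n_blocks)
    block_sums = mono[:, : m].reshape(len(subsets), n_blocks, block_len).sum(axis=2)
    rep_means = (w @ block_sums.T) / m  # (n_boot, n_mono)
    reps = _cumulant_from_moments(
        {frozenset(s): rep_means[:, si] for si, s in enumerate(subsets)}, k
    )
    return float(est), np.asarray(reps)


def _lag_columns(binned: BinnedCounts, indices, lags) -> List[np.ndarray]:
    offs = [0] + [int(l) for l in lags]
    lo = max(0, -min(offs))
    hi = binned.n_bins - max(0, max(offs))
    if hi - lo < 30:
        raise EstimationError("fewer than 30 valid bins; estimate refused")
    return [binned.counts[i - 1, lo + o : hi + o] for i, o in zip(indices, offs)]


# ---------------------------------------------------------------------------
# Density and count-cumulant estimators
# ---------------------------------------------------------------------------

def cumulant_density_at(
    binned: BinnedCounts,
    indices: Sequence[int],
    lag_vectors,
    n_boot: int = 200,
    block_len: int = 10,
    rng: Optional[np.random.Generator] = None,
    _return_reps: bool = False,
):
    """Cumulant-density estimates at arbitrary integer lag vectors.

    ``lag_vectors`` is ``(n_points, k-1)`` in units of bins (offsets of each
    later train relative to the first).  Returns ``(values, se)`` arrays; the
    estimate at each point is the binned joint cumulant divided by ``dt^k``.
    """
    idx = [int(i) for i in indices]
    k = len(idx)
    lag_vectors = np.atleast_2d(np.asarray(lag_vectors, dtype=int))
    if lag_vectors.shape[1] != k - 1:
        raise EstimationError("lag vectors must have k-1 entries")
    weights = None
    if n_boot:
        weights = _WeightCache(n_boot, rng if rng is not None else np.random.default_rng())
    scale = binned.dt**k
    vals = np.empty(lag_vectors.shape[0])
    ses = np.full(lag_vectors.shape[0], np.nan)
    reps_out = []
    for pi, lags in enumerate(lag_vectors):
        cols = _lag_columns(binned, idx, lags)
        est, reps = _plugin_with_reps(cols, weights, block_len)
        vals[pi] = est / scale
        if reps is not None:
            reps = reps / scale
            ses[pi] = reps.std(ddof=1)
            reps_out.append(reps)
    if _return_reps:
        return vals, ses, (np.stack(reps_out) if reps_out else None)
    return vals, ses


def cumulant_density_estimate(
    binned: BinnedCounts,
    indices: Sequence[int],
    lag_axes: Sequence[Sequence[int]],
    n_boot: int = 200,
    block_len: int = 10,
    rng: Optional[np.random.Generator] = None,
) -> CumulantDensity:
    """Cumulant density on the product grid of integer-bin ``lag_axes``."""
    idx = tuple(int(i) for i in indices)
    axes_bins = [np.asarray(a, dtype=int) for a in lag_axes]
    mesh = np.meshgrid(*axes_bins, indexing="ij")
    pts = np.stack([g.ravel() for g in mesh], axis=-1)
    vals, ses = cumulant_density_at(binned, idx, pts, n_boot, block_len, rng)
    shape = tuple(len(a) for a in axes_bins)
    return CumulantDensity(
        indices=idx,
        axes=tuple(a * binned.dt for a in axes_bins),
        values=vals.reshape(shape),
        se=ses.reshape(shape),
    )


def population_cumulant_estimate(
    binned: BinnedCounts,
    indices: Sequence[int],
    lag_axes: Sequence[Sequence[int]],
    n_boot: int = 200,
    block_len: int = 10,
    rng: Optional[np.random.Generator] = None,
) -> CumulantDensity:
    """Population cumulant density estimate: the cross-density summed over
    all non-reference trains (pooling for variance reduction).  Bootstrap
    replicates share block resamples across the pooled terms, so the
    reported SE respects their correlation."""
    idx = tuple(int(i) for i in indices)
    rest = [j for j in range(1, binned.n_trains + 1) if j not in idx]
    if not rest:
        raise EstimationError("population is empty")
    axes_bins = [np.asarray(a, dtype=int) for a in lag_axes]
    mesh = np.meshgrid(*axes_bins, indexing="ij")
    pts = np.stack([g.ravel() for g in mesh], axis=-1)
    rng = rng if rng is not None else np.random.default_rng()
    weights = _WeightCache(n_boot, rng) if n_boot else None

    total_vals = np.zeros(pts.shape[0])
    total_reps = None
    scale = binned.dt ** (len(idx) + 1)
    for j in rest:
        for pi, lags in enumerate(pts):
            cols = _lag_columns(binned, list(idx) + [j], lags)
            est, reps = _plugin_with_reps(cols, weights, block_len)
            total_vals[pi] += est / scale
            if reps is not None:
                if total_reps is None:
                    total_reps = np.zeros((pts.shape[0], len(reps)))
                total_reps[pi] += reps / scale
    ses = total_reps.std(axis=1, ddof=1) if total_reps is not None else np.full(pts.shape[0], np.nan)
    shape = tuple(len(a) for a in axes_bins)
    return CumulantDensity(
        indices=idx,
        axes=tuple(a * binned.dt for a in axes_bins),
        values=total_vals.reshape(shape),
        se=ses.reshape(shape),
    )


def spike_count_cumulant(
    spikes: SpikeTrainSet,
    indices: Sequence[int],
    T: float,
    n_boot: int = 0,
    rng: Optional[np.random.Generator] = None,
):
    """Spike-count cumulant ``gamma(T)``: the window is tiled into length-T
    segments, the joint cumulant of segment counts is divided by ``T``.
    Converges to ``lambda * pbar_D`` as ``T`` grows.  Returns the value, or
    ``(value, se)`` when ``n_boot > 0`` (bootstrap over segments)."""
    T = float(T)
    if T <= 0 or T > spikes.duration:
        raise EstimationError("segment length must lie in (0, window length]")
    n_seg = int(np.floor(spikes.duration / T))
    if n_seg < 10:
        raise EstimationError("fewer than 10 segments; estimate refused")
    idx = [int(i) for i in indices]
    edges = spikes.t_start + np.arange(n_seg + 1) * T
    cols = []
    for i in idx:
        c, _ = np.histogram(spikes.trains[i - 1], bins=edges)
        cols.append(c)
    weights = None
    if n_boot:
        weights = _WeightCache(n_boot, rng if rng is not None else np.random.default_rng())
    est, reps = _plugin_with_reps(cols, weights, block_len=1)
    if n_boot:
        return est / T, float(np.std(reps / T, ddof=1))
    return est / T
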