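"""Exact cumulant quantities of a GTaS model.

The k-th order cross-cumulant density of trains ``(i_1 .. i_k)`` is

    kappa(tau_1, .., tau_{k-1})
        = lambda * sum_{D' >= {i_1..i_k}} p_D' * q_Z^{D'}(tau)

where ``q_Z^{D'}`` is the density of the shift difference vector
``(Y_{i_2}-Y_{i_1}, .., Y_{i_k}-Y_{i_1})`` under ``Q_{D'}``.  Point-mass
shifts contribute delta atoms, which are kept symbolically (never binned
onto the grid).  Integrating over all lags gives the infinite-window
spike-count cumulant ``lambda * pbar_{D}``, independent of the shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import integrate, stats

from .model import GTaSModel, canonical_subset, tail_probability
from .shifts import (
    GaussianShift,
    NoClosedDensityError,
    _CumsumShift,
    hypoexp_pdf,
)


class AnalyticDensityUnavailable(ValueError):
    """A contributing marking's shift law has no evaluable density."""


@dataclass
class CumulantDensity:
    """Cross-cumulant density values on a rectangular lag grid.

    ``axes`` are the ``k-1`` strictly increasing lag axes (lag of train
    ``indices[m+1]`` relative to ``indices[0]``); ``values`` has shape
    ``tuple(len(a) for a in axes)``.  ``atoms`` carries the singular part as
    ``(lag-vector, mass)`` pairs.  ``se`` is populated by estimators only.
    """

    indices: Tuple[int, ...]
    axes: Tuple[np.ndarray, ...]
    values: np.ndarray
    atoms: List[Tuple[np.ndarray, float]] = field(default_factory=list)
    se: Optional[np.ndarray] = None

    def __post_init__(self):
        for a in self.axes:
            if len(a) > 1 and np.any(np.diff(a) <= 0):
                raise ValueError("lag axes must be strictly increasing")

    @property
    def order(self) -> int:
        return len(self.indices)

    @property
    def singular_mass(self) -> float:
        return float(sum(m for _, m in self.atoms))

    def integral(self) -> float:
        """Grid trapezoid of the smooth part plus the atom masses."""
        v = self.values
        for a in reversed(self.axes):
            v = np.trapezoid(v, x=a, axis=-1)
        return float(v) + self.singular_mass


def _contributing_markings(model: GTaSModel, indices):
    target = set(indices)
    return [(d, p) for d, p in model.markings.items() if target.issubset(d)]


def cross_cumulant_density(
    model: GTaSModel,
    indices: Sequence[int],
    axes: Sequence[np.ndarray],
) -> CumulantDensity:
    """Order-``k`` cross-cumulant density of distinct trains ``indices`` on
    the product grid spanned by ``axes`` (``k-1`` lag axes)."""
    idx = tuple(int(i) for i in indices)
    canonical_subset(idx, model.n_trains)  # distinctness / range check
    k = len(idx)
    if k < 2:
        raise ValueError("cross-cumulant density requires order >= 2")
    axes = tuple(np.asarray(a, dtype=float) for a in axes)
    if len(axes) != k - 1:
        raise ValueError(f"need {k - 1} lag axes for order {k}")
    mesh = np.meshgrid(*axes, indexing="ij")
    taus = np.stack(mesh, axis=-1)
    values = np.zeros(taus.shape[:-1])
    atoms: List[Tuple[np.ndarray, float]] = []
    lam = model.mother_rate
    for d, p in _contributing_markings(model, idx):
        dist = model.shifts[d]
        if dist.is_singular:
            for vec, mass in dist.difference_atoms(idx):
                atoms.append((np.asarray(vec, dtype=float), lam * p * mass))
            continue
        try:
            values = values + lam * p * dist.difference_density(idx, taus)
        except NoClosedDensityError as exc:
            raise AnalyticDensityUnavailable(
                f"marking {d} has no evaluable density ({dist.kind}); "
                "use the empirical estimator instead"
            ) from exc
    return CumulantDensity(indices=idx, axes=axes, values=values, atoms=atoms)


def cross_cumulant_density_fn(model: GTaSModel, indices) -> Callable[[np.ndarray], np.ndarray]:
    """The smooth part of the cross-cumulant density as a callable on lag
    vectors of shape ``(..., k-1)`` (atoms excluded)."""
    idx = tuple(int(i) for i in indices)
    canonical_subset(idx, model.n_trains)
    lam = model.mother_rate
    smooth = [
        (p, model.shifts[d])
        for d, p in _contributing_markings(model, idx)
        if not model.shifts[d].is_singular
    ]

    def fn(taus):
        taus = np.asarray(taus, dtype=float)
        out = np.zeros(taus.shape[:-1])
        for p, dist in smooth:
            out = out + lam * p * dist.difference_density(idx, taus)
        return out

    return fn


def infinite_window_cumulant(model: GTaSModel, indices) -> float:
    """Total integral of the cumulant density: exactly ``lambda * pbar_D``
    (the shift laws drop out)."""
    key = canonical_subset(indices, model.n_trains)
    return model.mother_rate * tail_probability(model, key)


def total_cumulant_mass(model: GTaSModel, indices, quad_tol: float = 1e-10) -> float:
    """Total cumulant mass by adaptive quadrature of each contributing
    marking's difference density (plus the atom masses).

    Unlike :meth:`CumulantDensity.integral` this does not depend on a finite
    grid, so it resolves the cone-boundary discontinuities of cascade
    densities; it should reproduce :func:`infinite_window_cumulant`.
    """
    idx = tuple(int(i) for i in indices)
    canonical_subset(idx, model.n_trains)
    k = len(idx)
    lam = model.mother_rate
    total = 0.0
    for d, p in _contributing_markings(model, idx):
        dist = model.shifts[d]
        if dist.is_singular:
            total += lam * p * sum(m for _, m in dist.difference_atoms(idx))
        elif isinstance(dist, _CumsumShift):
            # gaps between consecutive coordinates are independent: the lag
            # integral factorizes into 1-D integrals of each gap density
            order = np.argsort(idx)
            cs = [idx[j] - 1 for j in order]
            mass = 1.0
            for m in range(1, len(cs)):
                val, _ = integrate.quad(
                    lambda x, lo=cs[m - 1], hi=cs[m]: dist._gap_pdf(x, lo, hi),
                    0.0, np.inf, epsabs=quad_tol, limit=200,
                )
                mass *= val
            total += lam * p * mass
        else:
            b = dist.abs_bound(1e-12)
            fn = lambda *t: float(dist.difference_density(idx, np.array(t)))
            val, _ = integrate.nquad(
                fn, [(-2 * b, 2 * b)] * (k - 1), opts={"epsabs": quad_tol, "limit": 200}
            )
            total += lam * p * val
    return total


def _interval_intersection(intervals):
    lo = max(a for a, _ in intervals)
    hi = min(b for _, b in intervals)
    return max(0.0, hi - lo)


def count_cumulant(model: GTaSModel, indices, windows) -> float:
    """Joint cumulant of the spike counts ``X_{i_m}(A_m)`` on finite windows.

    Equal to ``lambda * sum_{D' >= D} p_D' * Integral_t P(t + Y_D in
    A_1 x .. x A_k) dt``.  Repeated indices are reduced by intersecting
    their windows (valid for GTaS: every joint cumulant of the underlying
    independent Poisson components equals its mean).  Smooth-shift quadrature
    is implemented for k <= 3; point-mass shifts are exact at any order.
    """
    idx = [int(i) for i in indices]
    wins = [(float(a), float(b)) for a, b in windows]
    if len(idx) != len(wins):
        raise ValueError("one window per index is required")
    # reduce repeats: intersect windows of the same train
    reduced = {}
    for i, (a, b) in zip(idx, wins):
        if i in reduced:
            reduced[i] = (max(reduced[i][0], a), min(reduced[i][1], b))
        else:
            reduced[i] = (a, b)
    idx = list(reduced)
    wins = [reduced[i] for i in idx]
    if any(b <= a for a, b in wins):
        return 0.0
    canonical_subset(idx, model.n_trains)
    k = len(idx)
    lam = model.mother_rate
    if k == 1:
        return lam * tail_probability(model, idx) * (wins[0][1] - wins[0][0])

    total = 0.0
    for d, p in _contributing_markings(model, idx):
        dist = model.shifts[d]
        if dist.is_singular:
            for vec, mass in dist.difference_atoms(idx):
                shifted = [wins[0]] + [
                    (a - vec[m], b - vec[m]) for m, (a, b) in enumerate(wins[1:])
                ]
                total += lam * p * mass * _interval_intersection(shifted)
            continue

        def overlap(taus):
            shifted = [wins[0]] + [
                (a - taus[m], b - taus[m]) for m, (a, b) in enumerate(wins[1:])
            ]
            return _interval_intersection(shifted)

        b0 = dist.abs_bound(1e-12)
        span = max(abs(x) for w in wins for x in w) + 2 * b0 + 1.0
        try:
            if k == 2:
                val, _ = integrate.quad(
                    lambda t: float(dist.difference_density(idx, np.array([t]))) * overlap([t]),
                    -span, span, limit=400,
                )
            elif k == 3:
                val, _ = integrate.dblquad(
                    lambda t2, t1: float(dist.difference_density(idx, np.array([t1, t2])))
                    * overlap([t1, t2]),
                    -span, span, -span, span,
                )
            else:
                raise NotImplementedError(
                    "smooth-shift count cumulants implemented for k <= 3; "
                    "use cross_cumulant_density and integrate"
                )
        except NoClosedDensityError as exc:
            raise AnalyticDensityUnavailable(
                f"marking {d} has no evaluable density ({dist.kind})"
            ) from exc
        total += lam * p * val
    return total


def population_cumulant_density(
    model: GTaSModel,
    indices: Sequence[int],
    axes: Sequence[np.ndarray],
) -> CumulantDensity:
    """Order-``k`` population cumulant density for ``k-1`` reference trains:
    the cross-cumulant density summed over every other train in the
    population (a pooled, spike-triggered measure)."""
    idx = tuple(int(i) for i in indices)
    canonical_subset(idx, model.n_trains)
    axes = tuple(np.asarray(a, dtype=float) for a in axes)
    rest = [j for j in range(1, model.n_trains + 1) if j not in idx]
    if not rest:
        raise ValueError("population is empty: all trains are reference trains")
    values = None
    atoms: List[Tuple[np.ndarray, float]] = []
    for j in rest:
        cd = cross_cumulant_density(model, idx + (j,), axes)
        values = cd.values if values is None else values + cd.values
        atoms.extend(cd.atoms)
    return CumulantDensity(indices=idx, axes=axes, values=values, atoms=atoms)


def cascade_closed_form(alphas, lambda_pop: float, subset, taus) -> np.ndarray:
    """Closed-form cross-cumulant density of the exponential cascade for an
    ascending train subset: ``lambda*p_pop`` times the product of
    hypoexponential gap densities between consecutive subset members.

    For the full set this is the product of ``alpha_{i+1}
    exp(-alpha_{i+1}(tau_i - tau_{i-1}))`` terms on the ordered cone.
    """
    alphas = np.asarray(alphas, dtype=float)
    if np.any(alphas <= 0):
        raise ValueError("rates must be positive")
    sub = tuple(int(i) for i in subset)
    if any(b <= a for a, b in zip(sub, sub[1:])):
        raise ValueError("subset must be strictly ascending")
    if sub[0] < 1 or sub[-1] > alphas.size:
        raise ValueError("subset outside 1..N")
    taus = np.asarray(taus, dtype=float)
    if taus.shape[-1] != len(sub) - 1:
        raise ValueError("lag vector length must be k-1")
    lags = np.concatenate([np.zeros(taus.shape[:-1] + (1,)), taus], axis=-1)
    vals = np.full(taus.shape[:-1], float(lambda_pop))
    for m in range(1, len(sub)):
        rates = alphas[sub[m - 1] : sub[m]]
        vals = vals * hypoexp_pdf(lags[..., m] - lags[..., m - 1], rates)
    return vals


def bin_averaged_density(fn, lag_vectors, dt: float, sub: int = 9) -> np.ndarray:
    """Expected value of a width-``dt`` binned plug-in density estimator at
    integer lag vectors: the density convolved with the product triangular
    kernel of half-width ``dt`` (approximated on a ``sub``-point rule).

    ``fn`` maps lag arrays of shape ``(..., k-1)`` to density values;
    ``lag_vectors`` is an ``(n, k-1)`` array of integer bin offsets.
    """
    lag_vectors = np.atleast_2d(np.asarray(lag_vectors, dtype=float))
    km1 = lag_vectors.shape[1]
    u = (np.arange(sub) + 0.5) / sub * 2.0 - 1.0  # midpoints of (-1, 1)
    grids = np.meshgrid(*([u] * km1), indexing="ij")
    weights = np.ones(grids[0].shape)
    for g in range(km1):
        widx = np.abs(grids[g])
        weights = weights * (1.0 - widx)
    weights = weights / weights.sum()
    offs = np.stack([g.ravel() for g in grids], axis=-1) * dt  # (sub^d, k-1)
    pts = lag_vectors[:, None, :] * dt + offs[None, :, :]
    vals = fn(pts)
    return np.sum(vals * weights.ravel()[None, :], axis=1)
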