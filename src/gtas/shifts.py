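"""Multivariate shift (jitter) distributions.

Each marking ``D`` of a GTaS model carries a distribution ``Q_D`` over
``R^N`` from which a shift vector ``Y`` is drawn per mother event; the copy of
the event assigned to train ``i in D`` lands at ``t + Y_i``.  Only the
coordinates of ``Y`` with indices in ``D`` are ever consumed.

Cumulant densities of the model are weighted sums of *difference-vector*
densities: the law of ``(Y_{i2}-Y_{i1}, ..., Y_{ik}-Y_{i1})``.  The classes
here expose that density directly; point-mass (delta) shifts carry it as a
symbolic list of atoms instead of numeric values.

Coordinate indices in this module are 1-based, matching train indices.
"""

from __future__ import annotations

import abc
import math

import numpy as np
from scipy import stats
from scipy.linalg import expm
from scipy.optimize import brentq


class NoClosedDensityError(ValueError):
    """Density evaluation requested for a sampling-only distribution."""


class SingularDensityError(ValueError):
    """Numeric density requested where the law is purely atomic."""


# ---------------------------------------------------------------------------
# Hypoexponential helpers (law of a sum of independent exponentials).
# Not provided by scipy; needed in closed form for the cascade shift family.
# ---------------------------------------------------------------------------

def _rates_distinct(rates: np.ndarray) -> bool:
    r = np.sort(rates)
    return bool(np.all(np.diff(r) > 1e-8 * r[-1]))


def _rates_equal(rates: np.ndarray) -> bool:
    return bool(np.ptp(rates) <= 1e-12 * rates.max())


def _partial_fraction_weights(rates: np.ndarray) -> np.ndarray:
    w = np.ones_like(rates)
    for i in range(rates.size):
        for j in range(rates.size):
            if i != j:
                w[i] *= rates[j] / (rates[j] - rates[i])
    return w


def _hypoexp_generator(rates: np.ndarray) -> np.ndarray:
    m = np.diag(-rates).astype(float)
    if rates.size > 1:
        m += np.diag(rates[:-1], 1)
    return m


def hypoexp_pdf(t, rates):
    """Density of ``sum_i T_i`` with independent ``T_i ~ Exp(rates[i])``.

    Uses the Erlang form for equal rates, partial fractions for well-separated
    rates, and a matrix-exponential evaluation otherwise (stable for clustered
    rates).
    """
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    if np.any(rates <= 0):
        raise ValueError("hypoexponential rates must be positive")
    t = np.asarray(t, dtype=float)
    if rates.size == 1 or _rates_equal(rates):
        return stats.gamma.pdf(t, a=rates.size, scale=1.0 / rates[0])
    if _rates_distinct(rates):
        w = _partial_fraction_weights(rates)
        tt = t[..., None]
        with np.errstate(over="ignore"):
            vals = np.sum(w * rates * np.exp(-rates * np.where(tt < 0, 0.0, tt)), axis=-1)
        return np.where(t >= 0, vals, 0.0)
    # clustered-but-not-identical rates: phase-type matrix exponential
    m = _hypoexp_generator(rates)
    flat = np.atleast_1d(t).ravel()
    out = np.zeros(flat.shape)
    for k, tk in enumerate(flat):
        if tk >= 0:
            out[k] = expm(m * tk)[0, -1] * rates[-1]
    return out.reshape(np.shape(t)) if np.shape(t) else float(out[0])


def hypoexp_cdf(t, rates):
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    if np.any(rates <= 0):
        raise ValueError("hypoexponential rates must be positive")
    t = np.asarray(t, dtype=float)
    if rates.size == 1 or _rates_equal(rates):
        return stats.gamma.cdf(t, a=rates.size, scale=1.0 / rates[0])
    if _rates_distinct(rates):
        w = _partial_fraction_weights(rates)
        tt = t[..., None]
        with np.errstate(over="ignore"):
            vals = 1.0 - np.sum(w * np.exp(-rates * np.where(tt < 0, 0.0, tt)), axis=-1)
        return np.where(t >= 0, vals, 0.0)
    m = _hypoexp_generator(rates)
    flat = np.atleast_1d(t).ravel()
    out = np.zeros(flat.shape)
    for k, tk in enumerate(flat):
        if tk >= 0:
            out[k] = 1.0 - expm(m * tk)[0, :].sum()
    return out.reshape(np.shape(t)) if np.shape(t) else float(out[0])


def hypoexp_ppf(q: float, rates) -> float:
    """Quantile by bracketed root finding; the Gamma(n, 1/min(rates))
    quantile stochastically dominates and supplies the upper bracket."""
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    if not 0.0 < q < 1.0:
        raise ValueError("quantile level must be in (0, 1)")
    hi = stats.gamma.ppf(q, a=rates.size, scale=1.0 / rates.min())
    return brentq(lambda t: hypoexp_cdf(t, rates) - q, 0.0, hi * 1.0000001, xtol=1e-12)


# ---------------------------------------------------------------------------
# Univariate marginals (used by GTaSModel mixture shifts)
# ---------------------------------------------------------------------------

class Atom1D:
    """A univariate point mass."""

    is_singular = True

    def __init__(self, loc: float):
        self.loc = float(loc)

    def rvs(self, size=None, random_state=None):
        return np.full(size if size is not None else (), self.loc)

    def pdf(self, x):
        raise SingularDensityError("point mass has no numeric density")

    def mean(self):
        return self.loc

    def __eq__(self, other):
        return isinstance(other, Atom1D) and other.loc == self.loc


class Hypoexp1D:
    """Law of a cumulative sum of independent exponentials."""

    is_singular = False

    def __init__(self, rates):
        self.rates = np.atleast_1d(np.asarray(rates, dtype=float))
        if np.any(self.rates <= 0):
            raise ValueError("rates must be positive")

    def rvs(self, size=None, random_state=None):
        rng = random_state if random_state is not None else np.random.default_rng()
        n = size if size is not None else 1
        draws = rng.exponential(1.0 / self.rates, size=(n, self.rates.size))
        out = draws.sum(axis=1)
        return out if size is not None else float(out[0])

    def pdf(self, x):
        return hypoexp_pdf(x, self.rates)

    def cdf(self, x):
        return hypoexp_cdf(x, self.rates)

    def mean(self):
        return float(np.sum(1.0 / self.rates))


class Mixture1D:
    """Finite mixture of univariate components (weights sum to one)."""

    def __init__(self, weights, components):
        self.weights = np.asarray(weights, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-9 or np.any(self.weights < 0):
            raise ValueError("mixture weights must be a probability vector")
        self.components = list(components)

    @property
    def is_singular(self):
        return any(getattr(c, "is_singular", False) for c in self.components)

    def rvs(self, size, random_state):
        which = random_state.choice(len(self.components), size=size, p=self.weights)
        out = np.empty(size, dtype=float)
        for i, comp in enumerate(self.components):
            sel = which == i
            if sel.any():
                out[sel] = comp.rvs(size=int(sel.sum()), random_state=random_state)
        return out

    def pdf(self, x):
        return sum(w * c.pdf(x) for w, c in zip(self.weights, self.components))

    def mean(self):
        return float(sum(w * c.mean() for w, c in zip(self.weights, self.components)))


# ---------------------------------------------------------------------------
# Multivariate shift distributions
# ---------------------------------------------------------------------------

def _coords_to_zero_based(coords, dim):
    c = tuple(int(i) for i in coords)
    if len(c) == 0:
        raise ValueError("coordinate subset must be nonempty")
    if len(set(c)) != len(c):
        raise ValueError("coordinate indices must be distinct")
    if any(i < 1 or i > dim for i in c):
        raise ValueError(f"coordinate indices must lie in 1..{dim}")
    return tuple(i - 1 for i in c)


class ShiftDistribution(abc.ABC):
    """A samplable shift law ``Q`` on ``R^dim``.

    ``coords`` arguments are 1-based coordinate tuples (train indices).
    ``difference_density(coords, taus)`` evaluates the density of
    ``(Y_{c2}-Y_{c1}, ..., Y_{ck}-Y_{c1})``; ``taus`` has shape
    ``(..., k-1)``.  Purely atomic laws raise :class:`SingularDensityError`
    there and report their mass through ``difference_atoms``.
    """

    kind: str = ""
    is_singular = False

    def __init__(self, dim: int):
        self.dim = int(dim)
        if self.dim < 1:
            raise ValueError("dimension must be >= 1")

    @abc.abstractmethod
    def sample(self, count: int, rng: np.random.Generator) -> np.ndarray:
        """Return ``count`` IID draws as a ``(count, dim)`` array."""

    @abc.abstractmethod
    def to_params(self) -> dict:
        """JSON-serializable parameter dict (inverse of :func:`shift_from_spec`)."""

    def marginal_density(self, coords, y):
        raise NoClosedDensityError(f"{self.kind} shift has no closed joint density")

    def difference_density(self, coords, taus):
        raise NoClosedDensityError(f"{self.kind} shift has no closed difference density")

    def difference_atoms(self, coords):
        return []

    @abc.abstractmethod
    def abs_bound(self, mass_tol: float) -> float:
        """A bound ``b`` with ``P(|Y_i| > b) < mass_tol`` for every coordinate."""

    @abc.abstractmethod
    def marginal1d(self, i: int):
        """The univariate marginal law of coordinate ``i`` (1-based)."""

    def to_spec(self) -> dict:
        return {"type": self.kind, "params": self.to_params()}

    def __eq__(self, other):
        return (
            isinstance(other, ShiftDistribution)
            and self.dim == other.dim
            and self.to_spec() == other.to_spec()
        )

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"{type(self).__name__}(dim={self.dim}, {self.to_params()})"


class DeltaShift(ShiftDistribution):
    """Deterministic shift: point mass at ``offsets`` (default the origin).

    The zero-offset case yields exact synchrony across the marked trains, as
    in the SIP/MIP constructions.
    """

    kind = "delta"
    is_singular = True

    def __init__(self, dim: int, offsets=None):
        super().__init__(dim)
        if offsets is None:
            offsets = np.zeros(dim)
        self.offsets = np.asarray(offsets, dtype=float)
        if self.offsets.shape != (self.dim,):
            raise ValueError("offsets must have one entry per coordinate")
        if not np.all(np.isfinite(self.offsets)):
            raise ValueError("offsets must be finite")

    def sample(self, count, rng):
        return np.tile(self.offsets, (count, 1))

    def difference_density(self, coords, taus):
        raise SingularDensityError(
            "delta shift difference law is purely atomic; use difference_atoms()"
        )

    def difference_atoms(self, coords):
        c = _coords_to_zero_based(coords, self.dim)
        vec = self.offsets[list(c[1:])] - self.offsets[c[0]]
        return [(vec, 1.0)]

    def abs_bound(self, mass_tol):
        return float(np.max(np.abs(self.offsets)))

    def marginal1d(self, i):
        c = _coords_to_zero_based((i,), self.dim)[0]
        return Atom1D(self.offsets[c])

    def to_params(self):
        return {"offsets": self.offsets.tolist()}


class GaussianShift(ShiftDistribution):
    """Jointly Gaussian shifts with arbitrary mean and covariance."""

    kind = "gaussian"

    def __init__(self, dim: int, mean=None, cov=None, sigma=None):
        super().__init__(dim)
        self.mean = np.zeros(dim) if mean is None else np.asarray(mean, dtype=float)
        if cov is None:
            sigma = 1.0 if sigma is None else float(sigma)
            if sigma <= 0:
                raise ValueError("sigma must be positive")
            cov = sigma**2 * np.eye(dim)
        self.cov = np.asarray(cov, dtype=float)
        if self.mean.shape != (dim,) or self.cov.shape != (dim, dim):
            raise ValueError("mean/cov dimensions do not match")
        # fail early on a non-PSD covariance
        stats.multivariate_normal(mean=self.mean, cov=self.cov, allow_singular=False)

    def sample(self, count, rng):
        return rng.multivariate_normal(self.mean, self.cov, size=count, method="svd")

    def marginal_density(self, coords, y):
        c = list(_coords_to_zero_based(coords, self.dim))
        mvn = stats.multivariate_normal(self.mean[c], self.cov[np.ix_(c, c)])
        return mvn.pdf(np.asarray(y, dtype=float))

    def difference_density(self, coords, taus):
        c = _coords_to_zero_based(coords, self.dim)
        if len(c) < 2:
            raise ValueError("difference density needs at least two coordinates")
        k = len(c)
        L = np.zeros((k - 1, self.dim))
        for m, cm in enumerate(c[1:]):
            L[m, cm] = 1.0
            L[m, c[0]] -= 1.0
        mu = L @ self.mean
        sig = L @ self.cov @ L.T
        return stats.multivariate_normal(mu, sig).pdf(np.asarray(taus, dtype=float))

    def abs_bound(self, mass_tol):
        z = stats.norm.isf(mass_tol / 2.0)
        return float(np.max(np.abs(self.mean) + z * np.sqrt(np.diag(self.cov))))

    def marginal1d(self, i):
        c = _coords_to_zero_based((i,), self.dim)[0]
        return stats.norm(loc=self.mean[c], scale=math.sqrt(self.cov[c, c]))

    def to_params(self):
        return {"mean": self.mean.tolist(), "cov": self.cov.tolist()}


class _CumsumShift(ShiftDistribution):
    """Base for shifts ``Y_i = sum_{j<=i} T_j`` with independent positive
    increments: ordered ``Y_N >= ... >= Y_1 >= 0`` in every draw, and joint
    marginals that factor into independent gap laws."""

    def _gap_law(self, lo: int, hi: int):
        """Law of ``Y_hi - Y_lo`` (0-based, ``lo < hi``; ``lo = -1`` for ``Y_hi``)."""
        raise NotImplementedError

    def _gap_pdf(self, x, lo, hi):
        raise NotImplementedError

    def marginal_density(self, coords, y):
        c = _coords_to_zero_based(coords, self.dim)
        if any(b <= a for a, b in zip(c, c[1:])):
            raise ValueError("coordinates must be given in ascending order")
        y = np.asarray(y, dtype=float)
        vals = self._gap_pdf(y[..., 0], -1, c[0])
        for m in range(1, len(c)):
            vals = vals * self._gap_pdf(y[..., m] - y[..., m - 1], c[m - 1], c[m])
        return vals

    def difference_density(self, coords, taus):
        c = _coords_to_zero_based(coords, self.dim)
        if len(c) < 2:
            raise ValueError("difference density needs at least two coordinates")
        taus = np.asarray(taus, dtype=float)
        if taus.shape[-1] != len(c) - 1:
            raise ValueError("lag vector length must be k-1")
        # lags are relative to the first listed coordinate; re-express as
        # consecutive gaps in ascending coordinate order
        order = np.argsort(c)
        lags = np.concatenate([np.zeros(taus.shape[:-1] + (1,)), taus], axis=-1)
        lags = lags[..., order]
        cs = [c[j] for j in order]
        vals = np.ones(taus.shape[:-1])
        for m in range(1, len(cs)):
            vals = vals * self._gap_pdf(lags[..., m] - lags[..., m - 1], cs[m - 1], cs[m])
        return vals

    def marginal1d(self, i):
        c = _coords_to_zero_based((i,), self.dim)[0]
        return self._gap_law(-1, c)


class ExpCumsumShift(_CumsumShift):
    """Cascade shifts: ``Y_i = sum_{j<=i} T_j`` with ``T_j ~ Exp(alpha_j)``.

    Gaps between coordinates are hypoexponential; this is the synfire-like
    population shift of the exponential cascade model.
    """

    kind = "exp_cumsum"

    def __init__(self, dim: int, alphas):
        super().__init__(dim)
        self.alphas = np.asarray(alphas, dtype=float)
        if self.alphas.shape != (dim,):
            raise ValueError("one rate per coordinate is required")
        if np.any(self.alphas <= 0):
            raise ValueError("rates must be positive")

    def sample(self, count, rng):
        t = rng.exponential(1.0 / self.alphas, size=(count, self.dim))
        return np.cumsum(t, axis=1)

    def _gap_law(self, lo, hi):
        return Hypoexp1D(self.alphas[lo + 1 : hi + 1])

    def _gap_pdf(self, x, lo, hi):
        return hypoexp_pdf(x, self.alphas[lo + 1 : hi + 1])

    def abs_bound(self, mass_tol):
        return hypoexp_ppf(1.0 - mass_tol, self.alphas)

    def to_params(self):
        return {"alphas": self.alphas.tolist()}


class GammaCumsumShift(_CumsumShift):
    """Cascade shifts built from gamma increments.

    Each increment has mean ``mu_shift`` and standard deviation
    ``sigma_shift`` (gamma shape ``mu^2/sigma^2``, scale ``sigma^2/mu``),
    letting mean and variance of the per-neighbor delay be set independently.
    The degenerate ``sigma_shift = 0`` limit is a deterministic ladder and is
    represented by :class:`DeltaShift` (see ``special.make_gamma_cascade``).
    """

    kind = "gamma_cumsum"

    def __init__(self, dim: int, mu_shift: float, sigma_shift: float):
        super().__init__(dim)
        self.mu_shift = float(mu_shift)
        self.sigma_shift = float(sigma_shift)
        if self.mu_shift <= 0 or self.sigma_shift <= 0:
            raise ValueError("mu_shift and sigma_shift must be positive "
                             "(use a delta shift for the sigma=0 limit)")
        self.shape = self.mu_shift**2 / self.sigma_shift**2
        self.scale = self.sigma_shift**2 / self.mu_shift

    def sample(self, count, rng):
        t = rng.gamma(self.shape, self.scale, size=(count, self.dim))
        return np.cumsum(t, axis=1)

    def _gap_law(self, lo, hi):
        return stats.gamma(a=(hi - lo) * self.shape, scale=self.scale)

    def _gap_pdf(self, x, lo, hi):
        return stats.gamma.pdf(x, a=(hi - lo) * self.shape, scale=self.scale)

    def abs_bound(self, mass_tol):
        return float(stats.gamma.isf(mass_tol, a=self.dim * self.shape, scale=self.scale))

    def to_params(self):
        return {"mu_shift": self.mu_shift, "sigma_shift": self.sigma_shift}


class EmpiricalShift(ShiftDistribution):
    """Resampling from a stored table of shift vectors (sampling only)."""

    kind = "empirical"

    def __init__(self, dim: int, samples):
        super().__init__(dim)
        self.samples = np.asarray(samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != dim:
            raise ValueError("samples must be an (m, dim) table")
        if self.samples.shape[0] < 1:
            raise ValueError("at least one sample vector is required")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("sample table contains non-finite values")

    def sample(self, count, rng):
        rows = rng.integers(0, self.samples.shape[0], size=count)
        return self.samples[rows]

    def abs_bound(self, mass_tol):
        return float(np.max(np.abs(self.samples)))

    def marginal1d(self, i):
        c = _coords_to_zero_based((i,), self.dim)[0]
        col = self.samples[:, c]

        class _Resampler:
            is_singular = False

            def rvs(self, size, random_state):
                return random_state.choice(col, size=size, replace=True)

            def pdf(self, x):
                raise NoClosedDensityError("empirical shift has no closed density")

            def mean(self):
                return float(col.mean())

        return _Resampler()

    def to_params(self):
        return {"samples": self.samples.tolist()}

    @classmethod
    def from_table(cls, dim: int, path):
        """Load a whitespace-delimited numeric table of shift vectors."""
        return cls(dim, np.loadtxt(path, ndmin=2))


_SHIFT_KINDS = {
    "delta": DeltaShift,
    "gaussian": GaussianShift,
    "exp_cumsum": ExpCumsumShift,
    "gamma_cumsum": GammaCumsumShift,
    "empirical": EmpiricalShift,
}


def shift_from_spec(spec: dict, dim: int) -> ShiftDistribution:
    """Build a shift distribution from its JSON form ``{"type", "params"}``."""
    if not isinstance(spec, dict) or set(spec) - {"type", "params"}:
        raise ValueError(f"malformed shift spec: {spec!r}")
    kind = spec.get("type")
    if kind not in _SHIFT_KINDS:
        raise ValueError(f"unknown shift type {kind!r}")
    params = dict(spec.get("params", {}))
    if kind == "empirical" and "path" in params:
        return EmpiricalShift.from_table(dim, params.pop("path"))
    try:
        return _SHIFT_KINDS[kind](dim, **params)
    except TypeError as exc:
        raise ValueError(f"bad parameters for {kind} shift: {exc}") from exc
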