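"""Named GTaS constructions.

* SIP (single interaction process): independent private trains merged with
  one global train — all correlated events exactly synchronous.
* MIP (multiple interaction process): independent retention-thinning of one
  mother train with probability ``epsilon`` per train.
* Exponential cascade: singleton/pair markings plus a population-wide
  marking whose shifts are cumulative sums of independent exponentials —
  synfire-like activity, cells firing in index order.
* Gamma cascade / synchronous pair: identical rates and markings; only the
  population shift differs (gamma-sum ladder vs. exact synchrony), so all
  infinite-window cumulants of every order coincide.
"""

from __future__ import annotations

from typing import Dict, Mapping, Sequence, Tuple

import numpy as np

from .model import GTaSModel, ModelValidationError, SubsetKey, canonical_subset, validate_model
from .shifts import DeltaShift, ExpCumsumShift, GammaCumsumShift, GaussianShift


def make_sip(lambda_common: float, lambda_private: Sequence[float]) -> GTaSModel:
    """SIP: ``X_i = Z_i + Z_c`` with private rates ``lambda_private[i]`` and a
    shared global rate ``lambda_common``; all shifts are point masses at zero.
    """
    lam_c = float(lambda_common)
    lam_p = [float(x) for x in lambda_private]
    n = len(lam_p)
    if n < 1:
        raise ModelValidationError("at least one private rate is required")
    if lam_c < 0 or any(x < 0 for x in lam_p):
        raise ModelValidationError("rates must be nonnegative")
    lam = lam_c + sum(lam_p)
    if lam <= 0:
        raise ModelValidationError("total rate must be positive")
    delta = DeltaShift(n)
    markings: Dict[SubsetKey, float] = {}
    for i, li in enumerate(lam_p, start=1):
        if li > 0:
            markings[(i,)] = li / lam
    if lam_c > 0:
        markings[tuple(range(1, n + 1))] = lam_c / lam
    shifts = {k: delta for k in markings}
    return validate_model(n, lam, markings, shifts)


def make_mip(lambda_mother: float, epsilon: float, n_trains: int) -> Tuple[GTaSModel, float]:
    """MIP via retention: marking probabilities
    ``p_D = eps^|D| (1-eps)^(N-|D|)`` over all subsets, with the empty
    marking (an everywhere-deleted event, mass ``(1-eps)^N``) removed exactly
    by lowering the mother rate to ``lambda_m (1 - (1-eps)^N)`` and
    renormalizing.  Returns ``(model, deletion_mass)``.
    """
    lam_m = float(lambda_mother)
    eps = float(epsilon)
    n = int(n_trains)
    if lam_m <= 0:
        raise ModelValidationError("mother rate must be positive")
    if not 0.0 < eps <= 1.0:
        raise ModelValidationError("epsilon must lie in (0, 1]")
    if n < 1:
        raise ModelValidationError("n_trains must be >= 1")
    if n > 20:
        raise ModelValidationError("MIP enumerates 2^N subsets; N > 20 refused")
    deletion_mass = (1.0 - eps) ** n
    lam = lam_m * (1.0 - deletion_mass)
    delta = DeltaShift(n)
    markings: Dict[SubsetKey, float] = {}
    norm = 1.0 - deletion_mass
    # enumerate nonempty subsets via bitmasks
    for mask in range(1, 1 << n):
        key = tuple(i + 1 for i in range(n) if mask >> i & 1)
        markings[key] = eps ** len(key) * (1.0 - eps) ** (n - len(key)) / norm
    shifts = {k: delta for k in markings}
    return validate_model(n, lam, markings, shifts), deletion_mass


def _cascade_markings(
    n: int,
    p_single: Sequence[float],
    p_pair: Mapping,
    p_pop: float,
    pair_sigma: float,
) -> Tuple[Dict[SubsetKey, float], Dict[SubsetKey, object]]:
    p_single = [float(x) for x in p_single]
    if len(p_single) != n:
        raise ModelValidationError("one singleton probability per train is required")
    markings: Dict[SubsetKey, float] = {}
    shifts: Dict[SubsetKey, object] = {}
    delta = DeltaShift(n)
    for i, p in enumerate(p_single, start=1):
        if p > 0:
            markings[(i,)] = p
            shifts[(i,)] = delta
    gauss = GaussianShift(n, sigma=float(pair_sigma))
    for pair, p in p_pair.items():
        key = canonical_subset(pair, n)
        if len(key) != 2:
            raise ModelValidationError(f"{key} is not a pair marking")
        if float(p) > 0:
            markings[key] = float(p)
            shifts[key] = gauss
    if float(p_pop) > 0:
        markings[tuple(range(1, n + 1))] = float(p_pop)
    return markings, shifts


def make_exponential_cascade(
    lam: float,
    n_trains: int,
    p_single: Sequence[float],
    p_pair: Mapping,
    p_pop: float,
    alphas: Sequence[float],
    pair_sigma: float = 1.0,
) -> GTaSModel:
    """Cascade model: markings restricted to ``|D| <= 2`` or the full set;
    population shifts ``Y_i = sum_{j<=i} T_j`` with ``T_j ~ Exp(alphas[j])``
    (ordered ``Y_N >= ... >= Y_1 >= 0``), pair shifts zero-mean Gaussian,
    singleton shifts point masses."""
    n = int(n_trains)
    if n < 4:
        raise ModelValidationError("the cascade construction requires N >= 4")
    markings, shifts = _cascade_markings(n, p_single, p_pair, p_pop, pair_sigma)
    full = tuple(range(1, n + 1))
    if full in markings:
        shifts[full] = ExpCumsumShift(n, alphas)
    return validate_model(n, float(lam), markings, shifts)


def make_gamma_cascade(
    lam: float,
    n_trains: int,
    p_single: Sequence[float],
    p_pair: Mapping,
    p_pop: float,
    mu_shift: float,
    sigma_shift: float,
    pair_sigma: float = 1.0,
) -> GTaSModel:
    """Cascade with gamma-sum population shifts: per-neighbor delay mean
    ``mu_shift`` and SD ``sigma_shift`` set independently.  The
    ``sigma_shift = 0`` limit is the deterministic ladder ``Y_i = i * mu``.
    """
    n = int(n_trains)
    if n < 4:
        raise ModelValidationError("the cascade construction requires N >= 4")
    mu, sig = float(mu_shift), float(sigma_shift)
    if mu <= 0 or sig < 0:
        raise ModelValidationError("mu_shift must be positive, sigma_shift nonnegative")
    markings, shifts = _cascade_markings(n, p_single, p_pair, p_pop, pair_sigma)
    full = tuple(range(1, n + 1))
    if full in markings:
        if sig == 0.0:
            shifts[full] = DeltaShift(n, offsets=mu * np.arange(1, n + 1))
        else:
            shifts[full] = GammaCumsumShift(n, mu, sig)
    return validate_model(n, float(lam), markings, shifts)


def make_synchronous(
    lam: float,
    n_trains: int,
    p_single: Sequence[float],
    p_pair: Mapping,
    p_pop: float,
    pair_sigma: float = 1.0,
) -> GTaSModel:
    """Same markings as the cascades but with an exactly synchronous
    population shift (point mass at the origin): identical rates and
    infinite-window cumulants of every order, different temporal structure."""
    n = int(n_trains)
    if n < 4:
        raise ModelValidationError("the cascade construction requires N >= 4")
    markings, shifts = _cascade_markings(n, p_single, p_pair, p_pop, pair_sigma)
    full = tuple(range(1, n + 1))
    if full in markings:
        shifts[full] = DeltaShift(n)
    return validate_model(n, float(lam), markings, shifts)
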