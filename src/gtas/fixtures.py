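"""Deterministic small fixture models used by tests, demos and docs.

The published figure parameters for the cascade examples are not available,
so these are representative package defaults (documented in
``docs/methods.md``): population-wide events occur at roughly 0.09 per time
unit and each train fires at roughly 0.2 per time unit, large enough that
second- and third-order densities are measurable from 10^4 time-unit runs.
"""

from __future__ import annotations

from typing import Dict

from .model import GTaSModel, validate_model
from .shifts import DeltaShift
from .special import (
    make_exponential_cascade,
    make_gamma_cascade,
    make_mip,
    make_sip,
    make_synchronous,
)

#: exponential-cascade fixture geometry (synfire-like raster demo and the
#: reference model for estimator/analytics agreement)
CASCADE_N = 6
CASCADE_LAMBDA = 0.7
CASCADE_P_POP = 0.125
CASCADE_P_PAIR = {(1, 3): 0.05, (2, 4): 0.05, (3, 5): 0.05, (4, 6): 0.05}
CASCADE_P_SINGLE = [0.1125] * 6  # remaining mass, equal per train
CASCADE_ALPHAS = (1.0, 2.0, 1.0, 2.0, 1.0, 2.0)
CASCADE_PAIR_SIGMA = 1.0

#: LIF-experiment fixture pair geometry: prominent population events over a
#: sparse background (ring-adjacent pair markings), per-neighbor shift mean 2
#: and SD 0.3 membrane time constants; calibrated together with the ring
#: defaults by scripts/calibrate_caf.py
GAMMA_N = 6
GAMMA_LAMBDA = 0.2
GAMMA_P_POP = 0.5
GAMMA_P_PAIR = {
    (1, 2): 0.05, (2, 3): 0.05, (3, 4): 0.05,
    (4, 5): 0.05, (5, 6): 0.05, (1, 6): 0.05,
}
GAMMA_P_SINGLE = [0.2 / 6] * 6
GAMMA_PAIR_SIGMA = 1.0
CASCADE_MU_SHIFT = 2.0
CASCADE_SIGMA_SHIFT = 0.3


def fixture_models() -> Dict[str, GTaSModel]:
    """Named fixture collection.

    * ``sip_small`` — SIP, 4 trains, private rate 3 each, common rate 2.
    * ``mip_small`` — MIP, 3 trains, mother rate 100, retention 0.1.
    * ``cascade_exp_n6`` — exponential cascade (synfire-like rasters).
    * ``cascade_gamma_n6`` / ``synchronous_n6`` — matched pair sharing
      ``lambda`` and ``p_D`` exactly; only the population shift differs.
    * ``singleton_independent`` — 4 independent Poisson trains.
    """
    singleton = validate_model(
        4,
        2.0,
        {(i,): 0.25 for i in range(1, 5)},
        {(i,): DeltaShift(4) for i in range(1, 5)},
    )
    return {
        "sip_small": make_sip(2.0, [3.0, 3.0, 3.0, 3.0]),
        "mip_small": make_mip(100.0, 0.1, 3)[0],
        "cascade_exp_n6": make_exponential_cascade(
            CASCADE_LAMBDA, CASCADE_N, CASCADE_P_SINGLE, CASCADE_P_PAIR,
            CASCADE_P_POP, CASCADE_ALPHAS, CASCADE_PAIR_SIGMA,
        ),
        "cascade_gamma_n6": make_gamma_cascade(
            GAMMA_LAMBDA, GAMMA_N, GAMMA_P_SINGLE, GAMMA_P_PAIR,
            GAMMA_P_POP, CASCADE_MU_SHIFT, CASCADE_SIGMA_SHIFT,
            GAMMA_PAIR_SIGMA,
        ),
        "synchronous_n6": make_synchronous(
            GAMMA_LAMBDA, GAMMA_N, GAMMA_P_SINGLE, GAMMA_P_PAIR,
            GAMMA_P_POP, GAMMA_PAIR_SIGMA,
        ),
        "singleton_independent": singleton,
    }
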