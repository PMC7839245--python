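"""Invertible oxygen–hemoglobin dissociation model.

A single monotone saturation curve is shared by the synthetic blood-gas
generator and the shunt estimator so that quantities written by one can be
recovered exactly by the other.  The curve is a Hill equation

    S(P) = P**n / (P**n + P50**n)

with a half-saturation pressure ``P50`` of 30 mmHg and cooperativity
``n`` = 2.7, which is a reasonable approximation for rabbit blood.  Both
constants are arguments everywhere they are used.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

__all__ = ["o2_saturation", "po2_from_saturation", "po2_from_content"]

#: default Hill parameters (mmHg, dimensionless)
P50_DEFAULT = 30.0
HILL_N_DEFAULT = 2.7


def o2_saturation(po2, p50: float = P50_DEFAULT, n: float = HILL_N_DEFAULT):
    """Fractional hemoglobin saturation at oxygen tension ``po2`` (mmHg)."""
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 < 0):
        raise ValueError("po2 must be non-negative")
    pn = po2**n
    return pn / (pn + p50**n)


def po2_from_saturation(so2: float, p50: float = P50_DEFAULT,
                        n: float = HILL_N_DEFAULT) -> float:
    """Invert the Hill curve: tension (mmHg) at saturation ``so2``."""
    if not 0.0 <= so2 < 1.0:
        raise ValueError("saturation must lie in [0, 1)")
    if so2 == 0.0:
        return 0.0
    return p50 * (so2 / (1.0 - so2)) ** (1.0 / n)


def po2_from_content(content: float, hb: float, *,
                     hb_capacity: float = 1.34, solubility: float = 0.003,
                     p50: float = P50_DEFAULT, n: float = HILL_N_DEFAULT) -> float:
    """Oxygen tension (mmHg) at a given whole-blood content (mL O2/dL).

    Solves ``hb_capacity*hb*S(P) + solubility*P = content`` for P.  The left
    side is strictly increasing in P, so the root is unique.
    """
    if content < 0:
        raise ValueError("content must be non-negative")
    if content == 0.0:
        return 0.0

    def f(p):
        return hb_capacity * hb * o2_saturation(p, p50, n) + solubility * p - content

    hi = 800.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e7:
            raise ValueError("content not attainable at any physical po2")
    return brentq(f, 0.0, hi, xtol=1e-10, rtol=1e-14)
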