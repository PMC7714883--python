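"""Closed-form macroparameters derived from fitted rate constants and CBF.

These combine the water-scan flow estimate with ammonia-scan rate constants:
the Renkin-Crone permeability-surface area product, the first-pass
extraction fraction, the metabolic flux of ammonia into glutamine, the
distribution volume and the tissue washout half-life.
"""

from __future__ import annotations

import math
import warnings

__all__ = [
    "ps_product",
    "extraction_fraction",
    "flux_met",
    "volume_of_distribution",
    "washout_half_life",
]

LN2 = math.log(2.0)


def ps_product(cbf: float, K: float) -> float:
    """Renkin-Crone permeability-surface area product, mL/100 g/min.

    ``PS = -CBF ln(1 - K/CBF)`` inverts the single-capillary extraction
    relation ``K = CBF (1 - e^{-PS/CBF})``. Serves both PS_BBB (K = K1) and
    PS_met (K = K_met). When the measured clearance reaches or exceeds flow
    the extraction is saturated and PS is undefined: returns ``inf`` with a
    warning rather than raising, since noisy fits can produce K1 slightly
    above CBF.
    """
    if not (cbf > 0):
        raise ValueError("CBF must be positive")
    if K < 0:
        raise ValueError("clearance K must be non-negative")
    if K >= cbf:
        warnings.warn(
            f"clearance K={K:.3g} >= CBF={cbf:.3g}: extraction saturated, PS undefined",
            stacklevel=2,
        )
        return math.inf
    return -cbf * math.log1p(-K / cbf)


def extraction_fraction(K1: float, cbf: float) -> float:
    """First-pass extraction fraction EF = K1 / CBF."""
    if cbf == 0:
        raise ValueError("CBF must be nonzero")
    return K1 / cbf


def flux_met(Kmet: float, A: float) -> float:
    """Metabolic flux of ammonia from blood into glutamine, nmol/100 g/min.

    ``Flux_met = K_met * A`` with K_met in mL/100 g/min and the endogenous
    blood ammonia concentration A in umol/L (= nmol/mL), so the product is
    nmol/100 g/min.
    """
    if Kmet < 0 or A < 0:
        raise ValueError("Kmet and A must be non-negative")
    return Kmet * A


def volume_of_distribution(K1: float, k2: float) -> float:
    """Equilibrium distribution volume V_T = K1/k2, mL/100 g."""
    if k2 <= 0:
        raise ValueError("k2 must be positive for a finite V_T")
    return K1 / k2


def washout_half_life(k2: float) -> float:
    """Tissue washout half-life ln 2 / k2 in minutes; NaN if k2 <= 0."""
    if k2 <= 0:
        warnings.warn("k2 <= 0: washout half-life undefined", stacklevel=2)
        return math.nan
    return LN2 / k2
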