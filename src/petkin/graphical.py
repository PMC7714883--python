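"""Patlak graphical analysis of net irreversible uptake.

For a tracer with an irreversible compartment the transformed data

    y_i = C_t(t_i) / C_p(t_i)      x_i = int_0^{t_i} C_p(u) du / C_p(t_i)

become linear in x once the reversible compartments have equilibrated
(t >= t*); the slope is the net metabolic clearance K_met = K1 k3/(k2+k3)
and the intercept the effective initial distribution volume V0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .blood import SampledCurve
from .frames import FrameSchedule

__all__ = ["PatlakResult", "patlak"]


@dataclass(frozen=True)
class PatlakResult:
    """Late-time linear fit of the Patlak-transformed data.

    ``Kmet`` in mL/100 g/min (slope), ``intercept`` in mL/100 g (V0).
    """

    Kmet: float
    intercept: float
    r2: float
    n_points: int
    tstar: float

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("Patlak fit needs at least 2 points")
        if self.tstar < 0:
            raise ValueError("tstar must be non-negative")


def patlak(
    tac: np.ndarray,
    schedule: FrameSchedule,
    parent_plasma: SampledCurve,
    tstar: float = 20.0,
) -> PatlakResult:
    """Ordinary least squares on the Patlak plot over frames with t_i >= t*.

    The plasma running integral uses the trapezoid rule on the plasma grid;
    both axes are evaluated at frame mid-times. ``tstar`` in minutes
    (default 20, i.e. the last third of a 30-min acquisition).
    """
    tac = np.asarray(tac, dtype=float)
    if tac.size != schedule.n_frames:
        raise ValueError("TAC length does not match the frame schedule")
    mids = schedule.mids
    sel = mids >= tstar
    if int(sel.sum()) < 2:
        raise ValueError(f"fewer than 2 frames with mid-time >= t* = {tstar} min")
    cum = cumulative_trapezoid(parent_plasma.values, parent_plasma.times, initial=0.0)
    cp_mid = parent_plasma(mids[sel])
    if np.any(cp_mid <= 0):
        raise ValueError("plasma activity is zero within the Patlak fit window")
    x = np.interp(mids[sel], parent_plasma.times, cum) / cp_mid
    y = tac[sel] / cp_mid
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - yhat) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    # slope is per-mL-tissue clearance (1/min); report per 100 g tissue
    return PatlakResult(
        Kmet=float(slope * 100.0),
        intercept=float(intercept * 100.0),
        r2=r2,
        n_points=int(sel.sum()),
        tstar=float(tstar),
    )
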