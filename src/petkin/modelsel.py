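"""AIC model selection over the candidate family and identifiability testing.

With Gaussian residuals of unknown scale the least-squares AIC is
``n ln(WRSS/n) + 2p``; the minimum-AIC converged candidate is selected, ties
going to the simpler model. A rate constant is called identifiable when its
estimate is significantly greater than zero by a one-sided t-test on
``n_frames - n_params`` degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Protocol

from scipy import stats

__all__ = ["aic", "ModelComparison", "select_model", "IdentifiabilityResult", "identifiability_test"]


class _FitLike(Protocol):
    model_id: str
    wrss: float
    n_params: int
    n_frames: int
    converged: bool


def aic(wrss: float, n_frames: int, n_params: int, corrected: bool = False) -> float:
    """Least-squares Akaike information criterion.

    ``AIC = n ln(WRSS/n) + 2p`` with p counting every free parameter
    (including vB). ``corrected=True`` adds the small-sample AICc term
    ``2p(p+1)/(n-p-1)``. A perfect fit (WRSS = 0) returns -inf.
    """
    if wrss < 0:
        raise ValueError("WRSS must be non-negative")
    if n_frames <= n_params:
        raise ValueError("need more frames than parameters")
    if wrss == 0:
        return -math.inf
    value = n_frames * math.log(wrss / n_frames) + 2 * n_params
    if corrected:
        value += 2 * n_params * (n_params + 1) / (n_frames - n_params - 1)
    return value


@dataclass(frozen=True)
class ModelComparison:
    """Per-candidate AIC table with the selected model."""

    table: list[dict]  # one row per model: model_id, wrss, n_params, aic, delta_aic
    selected: str


#: Relative WRSS below which a fit counts as perfect to round-off; such fits
#: are indistinguishable and compete on parameter count alone.
_PERFECT_FIT_REL = 1e-25


def select_model(fits: Iterable[_FitLike], corrected: bool = False) -> ModelComparison:
    """Minimum-AIC selection across candidate fits.

    Non-converged fits are excluded; at least two converged candidates are
    required. AIC ties resolve to the model with fewer parameters. Fits whose
    WRSS is below double-precision resolution of the data (relative to the
    weighted sum of squares of the TAC itself) are floored to a common value,
    so on noise-free data the simplest perfectly fitting model wins.
    """
    usable = [f for f in fits if f.converged]
    if len(usable) < 2:
        raise ValueError("need at least 2 converged fits to compare models")
    floor = _PERFECT_FIT_REL * max(getattr(f, "wrss_scale", 0.0) for f in usable)
    rows = []
    for f in usable:
        wrss = max(f.wrss, floor)
        rows.append({
            "model_id": f.model_id,
            "wrss": f.wrss,
            "n_params": f.n_params,
            "aic": aic(wrss, f.n_frames, f.n_params, corrected=corrected),
        })
    best = min(rows, key=lambda r: (r["aic"], r["n_params"]))
    for r in rows:
        r["delta_aic"] = r["aic"] - best["aic"]
    return ModelComparison(table=rows, selected=best["model_id"])


@dataclass(frozen=True)
class IdentifiabilityResult:
    """One-sided t-test of a parameter estimate against zero."""

    parameter: str
    estimate: float
    se: float
    t: float
    df: int
    p_one_sided: float
    significant: bool


def identifiability_test(
    estimate: float,
    se: float,
    df: int,
    alpha: float = 0.05,
    parameter: str = "",
) -> IdentifiabilityResult:
    """Is the estimate significantly greater than zero?

    ``t = estimate/se`` referred to a t distribution on ``df`` degrees of
    freedom (``n_frames - n_params`` for an NLLS fit); one-sided p =
    P(T >= t). A zero standard error with a positive estimate is treated as
    perfectly identified (p = 0).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if se < 0:
        raise ValueError("se must be non-negative")
    if se == 0:
        if estimate > 0:
            return IdentifiabilityResult(parameter, estimate, se, math.inf, df, 0.0, True)
        raise ValueError("se = 0 with non-positive estimate")
    t = estimate / se
    p = float(stats.t.sf(t, df))
    return IdentifiabilityResult(parameter, estimate, se, t, df, p, p < alpha)
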