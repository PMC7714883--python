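"""Arterial input-function construction from sampled blood data.

The whole-blood curve comes from a continuous detector cross-calibrated
against manual samples; the metabolite-corrected parent-plasma input is
``Cp(t) = pob * f(t) * C_wb(t − delay)`` where ``pob`` is the mean
plasma-over-blood ratio, ``f`` the fitted biexponential parent fraction and
``delay`` the blood-sampling transit delay relative to the head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "SampledCurve",
    "ParentFractionFit",
    "InputFunction",
    "plasma_over_blood",
    "fit_parent_fraction",
    "estimate_delay",
    "calibrate_continuous",
    "build_parent_plasma_input",
]


@dataclass(frozen=True)
class SampledCurve:
    """Activity concentration sampled at strictly increasing times.

    ``times`` in minutes, ``values`` in kBq/mL.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.shape != values.shape or times.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        if times.size >= 2 and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation; zero before the first sample, flat after the last."""
        t = np.asarray(t, dtype=float)
        return np.interp(t, self.times, self.values, left=0.0)

    def shifted(self, delay_s: float) -> "SampledCurve":
        """The same physical curve observed ``delay_s`` seconds later."""
        return SampledCurve(self.times + delay_s / 60.0, self.values)


@dataclass(frozen=True)
class ParentFractionFit:
    """Biexponential parent-fraction model ``f(t) = A e^{−αt} + (1−A) e^{−βt}``.

    Constrained so f(0) = 1 (all tracer is parent at injection) with the fast
    component first: A ∈ [0, 1], α ≥ β ≥ 0 (1/min).
    """

    A: float
    alpha: float
    beta: float
    rss: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.A <= 1.0):
            raise ValueError("A must lie in [0, 1]")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("rate constants must be non-negative")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.A * np.exp(-self.alpha * t) + (1.0 - self.A) * np.exp(-self.beta * t)


@dataclass(frozen=True)
class InputFunction:
    """Whole-blood and parent-plasma input curves with their corrections."""

    whole_blood: SampledCurve
    parent_plasma: SampledCurve
    pob: float
    delay_s: float = 0.0

    def __post_init__(self) -> None:
        if not (self.pob > 0):
            raise ValueError("plasma-over-blood ratio must be positive")
        # parent fraction cannot exceed 1: Cp(t) <= pob * C_wb(t) on the grid
        wb_at = self.whole_blood(self.parent_plasma.times)
        excess = self.parent_plasma.values - self.pob * wb_at
        tol = 1e-6 * max(1.0, float(np.max(np.abs(wb_at), initial=0.0)))
        if np.any(excess > tol):
            raise ValueError("parent plasma exceeds pob * whole blood (parent fraction > 1)")


def plasma_over_blood(manual_samples: list[tuple[float, float]]) -> float:
    """Mean of per-sample plasma/whole-blood activity ratios."""
    if not manual_samples:
        raise ValueError("at least one manual sample pair is required")
    ratios = []
    for plasma, whole in manual_samples:
        if whole == 0:
            raise ValueError("whole-blood activity of zero in manual sample")
        ratios.append(plasma / whole)
    return float(np.mean(ratios))


def fit_parent_fraction(
    samples: list[tuple[float, float]] | np.ndarray,
) -> ParentFractionFit:
    """Least-squares biexponential fit to measured parent fractions.

    Accepts ``(time_min, fraction)`` pairs; fractions up to 1.05 are tolerated
    as measurement overshoot and clipped to 1. Box constraints: A in [0, 1],
    rates >= 0, with the fast/slow ordering alpha >= beta enforced by
    relabelling after the fit.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (time, fraction) samples")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite parent-fraction input")
    t, f = arr[:, 0], arr[:, 1]
    if np.any(f < 0) or np.any(f > 1.05):
        raise ValueError("fractions must lie in [0, 1.05]")
    f = np.minimum(f, 1.0)

    def resid(p: np.ndarray) -> np.ndarray:
        A, alpha, beta = p
        return A * np.exp(-alpha * t) + (1 - A) * np.exp(-beta * t) - f

    best = None
    # deterministic multi-starts across plausible fast/slow splits
    for A0, a0, b0 in [(0.6, 0.5, 0.05), (0.3, 1.0, 0.01), (0.9, 0.2, 0.0), (0.5, 0.0, 0.0)]:
        sol = least_squares(
            resid,
            x0=[A0, a0, b0],
            bounds=([0.0, 0.0, 0.0], [1.0, 20.0, 20.0]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    A, alpha, beta = best.x
    if alpha < beta:  # relabel so the fast component comes first
        A, alpha, beta = 1.0 - A, beta, alpha
    return ParentFractionFit(A=float(A), alpha=float(alpha), beta=float(beta),
                             rss=float(2 * best.cost))


def estimate_delay(
    whole_blood: SampledCurve,
    reference_tac: SampledCurve,
    search_s: tuple[float, float] = (-60.0, 60.0),
    step_s: float = 1.0,
) -> float:
    """Blood-sampling delay (seconds) by matching normalised leading edges.

    Automates the visual alignment of the blood rise with a grey-matter TAC:
    both curves are peak-normalised, and the squared mismatch over the
    reference's bolus rise (5% of peak up to the peak) is minimised over a
    1 s delay grid. Positive delay means the blood curve lags the tissue.
    """
    wb_peak = float(np.max(whole_blood.values))
    ref_peak = float(np.max(reference_tac.values))
    if wb_peak <= 0 or np.ptp(whole_blood.values) < 1e-12 * max(1.0, abs(wb_peak)):
        raise ValueError("whole-blood curve has no detectable rise")
    if ref_peak <= 0:
        raise ValueError("reference TAC has no detectable rise")

    ref_norm = reference_tac.values / ref_peak
    i_peak = int(np.argmax(ref_norm))
    rise = np.flatnonzero(ref_norm[: i_peak + 1] >= 0.05)
    if rise.size == 0:
        rise = np.array([i_peak])
    window = slice(int(rise[0]), i_peak + 1)
    t_ref = reference_tac.times[window]
    y_ref = ref_norm[window]

    delays = np.arange(search_s[0], search_s[1] + 0.5 * step_s, step_s)
    sse = np.empty_like(delays)
    for k, d in enumerate(delays):
        y_wb = whole_blood(t_ref + d / 60.0) / wb_peak
        sse[k] = float(np.sum((y_wb - y_ref) ** 2))
    return float(delays[int(np.argmin(sse))])


def calibrate_continuous(
    continuous: SampledCurve,
    manual: SampledCurve,
    scan_end_min: float,
    tail_points: int = 3,
) -> SampledCurve:
    """Cross-calibrate the continuous detector curve against manual samples
    and extend it to scan end.

    The continuous curve is rescaled by the median manual/continuous ratio at
    manual-sample times falling inside the continuous record, then extended to
    ``scan_end_min`` on a 1 s grid by a monoexponential fitted through the last
    ``tail_points`` manual samples.
    """
    t_end = continuous.times[-1]
    inside = manual.times <= t_end
    if not np.any(inside):
        raise ValueError("no manual samples overlap the continuous record")
    cont_at = continuous(manual.times[inside])
    ok = cont_at > 0
    if not np.any(ok):
        raise ValueError("continuous curve is zero at all overlapping manual samples")
    scale = float(np.median(manual.values[inside][ok] / cont_at[ok]))
    values = continuous.values * scale

    if t_end >= scan_end_min:
        return SampledCurve(continuous.times, values)

    tail = manual.values[-tail_points:]
    tail_t = manual.times[-tail_points:]
    if tail.size < 2 or np.any(tail <= 0):
        raise ValueError("need >= 2 positive manual tail samples to extrapolate")
    slope, intercept = np.polyfit(tail_t, np.log(tail), 1)
    dt = continuous.times[1] - continuous.times[0] if continuous.times.size > 1 else 1.0 / 60.0
    t_ext = np.arange(t_end + dt, scan_end_min + 0.5 * dt, dt)
    # blend: continue from the calibrated end value with the manual-tail decay rate
    v_end = values[-1]
    v_ext = v_end * np.exp(slope * (t_ext - t_end))
    _ = intercept  # amplitude comes from the continuous end point, not the manual fit
    return SampledCurve(
        np.concatenate([continuous.times, t_ext]),
        np.concatenate([values, v_ext]),
    )


def build_parent_plasma_input(
    whole_blood: SampledCurve,
    pob: float,
    pf: ParentFractionFit,
    delay_s: float = 0.0,
) -> InputFunction:
    """Assemble the metabolite-corrected parent-plasma input function.

    ``Cp(t) = pob * f(t) * C_wb(t + delay)`` evaluated on the whole-blood
    time grid: a positive ``delay_s`` (blood record lagging the tissue, as
    returned by :func:`estimate_delay`) advances the blood curve so the two
    are realigned. The whole-blood curve is shifted the same way so both
    components stay on the scanner clock.
    """
    t = whole_blood.times
    wb_shifted = whole_blood(t + delay_s / 60.0)
    parent = pob * pf(t) * wb_shifted
    return InputFunction(
        whole_blood=SampledCurve(t, wb_shifted),
        parent_plasma=SampledCurve(t, parent),
        pob=pob,
        delay_s=delay_s,
    )
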