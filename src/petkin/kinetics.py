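"""Forward simulation and weighted NLLS fitting of PET compartment models.

The candidate family for [13N]ammonia is nested: a reversible two-tissue
compartment model (2TCM) with blood-volume term,

    dC1/dt = K1*Cp - (k2 + k3)*C1 + k4*C2
    dC2/dt = k3*C1 - k4*C2
    C_PET(t) = (1 - vB)*(C1 + C2) + vB*C_wb(t)

with the simpler candidates obtained by fixing k4, k3, k2 to zero in turn.
[15O]water CBF uses the same one-tissue machinery on the whole-blood curve
with explicit delay and dispersion of the arterial input (Meyer's
free-diffusion model).

Convolutions are evaluated analytically against a piecewise-linear input on
the blood sampling grid, so forward curves are exact (to round-off) for the
tabulated input; frame values are interval means of the fine-grid curve.

Units: K1 and CBF in mL/100 g/min (tissue density 1 g/mL), rate constants in
1/min, times in minutes internally, activities in kBq/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares
from scipy.signal import lfilter

from .blood import InputFunction, SampledCurve
from .frames import FrameSchedule, Isotope

__all__ = [
    "ModelSpec",
    "KineticParams",
    "FitResult",
    "CBFResult",
    "CANDIDATE_MODELS",
    "PARAM_BOUNDS",
    "expconv",
    "frame_average",
    "frame_weights",
    "simulate_tissue_curve",
    "fit_compartment_model",
    "fit_candidate_models",
    "fit_meyer_cbf",
]

#: Fitting boxes shared by all models (units as in module docstring; delay/tau in s).
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "K1": (0.0, 100.0),
    "k2": (0.0, 1.0),
    "k3": (0.0, 1.0),
    "k4": (0.0, 1.0),
    "vB": (0.0, 0.2),
    "delay_s": (-15.0, 15.0),
    "tau_s": (0.0, 20.0),
}


@dataclass(frozen=True)
class ModelSpec:
    """Structure of a candidate compartment model.

    ``n_tissue`` is 1 or 2; ``reversible`` frees k2 (one-tissue) or k4
    (two-tissue); ``fit_delay_dispersion`` adds arterial delay and
    monoexponential dispersion as free parameters (the CBF model and the
    extended ammonia variant).
    """

    n_tissue: int
    reversible: bool
    fit_vB: bool = True
    fit_delay_dispersion: bool = False

    def __post_init__(self) -> None:
        if self.n_tissue not in (1, 2):
            raise ValueError("n_tissue must be 1 or 2")

    @property
    def model_id(self) -> str:
        base = f"{self.n_tissue}tcm_{'rev' if self.reversible else 'irr'}"
        return base + ("_dd" if self.fit_delay_dispersion else "")

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["K1"]
        if self.n_tissue == 2 or self.reversible:
            names.append("k2")
        if self.n_tissue == 2:
            names.append("k3")
            if self.reversible:
                names.append("k4")
        if self.fit_vB:
            names.append("vB")
        if self.fit_delay_dispersion:
            names += ["delay_s", "tau_s"]
        return tuple(names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)


#: The four nested candidates fitted to every ammonia TAC, simplest first.
CANDIDATE_MODELS: dict[str, ModelSpec] = {
    "1tcm_irr": ModelSpec(1, reversible=False),
    "1tcm_rev": ModelSpec(1, reversible=True),
    "2tcm_irr": ModelSpec(2, reversible=False),
    "2tcm_rev": ModelSpec(2, reversible=True),
}


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the (up to) two-tissue model plus blood fraction.

    K1 in mL/100 g/min; k2, k3, k4 in 1/min; vB unitless in [0, 0.2];
    delay_s / tau_s in seconds (used only by delay-dispersion variants).
    """

    K1: float
    k2: float = 0.0
    k3: float = 0.0
    k4: float = 0.0
    vB: float = 0.0
    delay_s: float = 0.0
    tau_s: float = 0.0

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "k4", "tau_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 <= self.vB <= 0.2):
            raise ValueError("vB must lie in [0, 0.2]")


@dataclass(frozen=True)
class FitResult:
    """A weighted NLLS fit of one candidate model to one TAC.

    ``wrss_scale`` is the weighted sum of squares of the data itself; model
    selection uses it to recognise fits that are perfect to round-off.
    """

    model_id: str
    params: KineticParams
    se: dict[str, float]
    cov: np.ndarray
    wrss: float
    n_frames: int
    n_params: int
    aic: float
    converged: bool
    wrss_scale: float = 0.0


@dataclass(frozen=True)
class CBFResult:
    """Meyer free-diffusion fit of a [15O]water TAC."""

    CBF: float
    k2p: float
    vB: float
    delay_s: float
    tau_s: float
    se: dict[str, float]
    wrss: float
    converged: bool


# ---------------------------------------------------------------------------
# forward model


def _segment_kernels(x: np.ndarray, h: np.ndarray, rate: float):
    """Exact integrals g0 = int_0^h e^{-a(h-s)} ds and
    g1 = int_0^h e^{-a(h-s)} (h-s) ds ... expressed so small a*h is stable."""
    g0 = np.empty_like(x)
    g1 = np.empty_like(x)
    small = x < 1e-3
    xl, hl = x[~small], h[~small]
    E = np.exp(-xl)
    g0[~small] = -np.expm1(-xl) / rate
    g1[~small] = (-np.expm1(-xl) - xl * E) / rate**2
    xs, hs = x[small], h[small]
    g0[small] = hs * (1 - xs / 2 + xs**2 / 6 - xs**3 / 24)
    g1[small] = hs**2 * (0.5 - xs / 3 + xs**2 / 8 - xs**3 / 30)
    return g0, g1


def expconv(times_min: np.ndarray, values: np.ndarray, rate: float) -> np.ndarray:
    """``y(t) = int_0^t exp(-rate (t-s)) u(s) ds`` for piecewise-linear u.

    Exact at the grid nodes. ``rate`` in 1/min, >= 0; rate 0 reduces to the
    running integral.
    """
    t = np.asarray(times_min, dtype=float)
    u = np.asarray(values, dtype=float)
    if t.size < 2:
        return np.zeros_like(u)
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if rate == 0.0:
        return cumulative_trapezoid(u, t, initial=0.0)
    h = np.diff(t)
    x = rate * h
    g0, g1 = _segment_kernels(x, h, rate)
    # contribution of segment k (u linear from u_k to u_{k+1}):
    incr = u[:-1] * g0 + (u[1:] - u[:-1]) * (g0 - g1 / h)
    E = np.exp(-x)
    y = np.empty_like(u)
    y[0] = 0.0
    if np.allclose(h, h[0], rtol=1e-9, atol=0.0):
        # uniform grid: the recurrence y_{k+1} = E y_k + incr_k is an IIR filter
        y[1:] = lfilter([1.0], [1.0, -float(E[0])], incr)
    else:
        acc = 0.0
        for k in range(h.size):
            acc = acc * E[k] + incr[k]
            y[k + 1] = acc
    return y


def _dispersed_delayed(curve: SampledCurve, delay_s: float, tau_s: float) -> np.ndarray:
    """Arterial curve seen by the tissue: advanced by ``delay_s`` (positive
    delay means the blood record lags the tissue, as in
    :func:`petkin.blood.estimate_delay`) and convolved with the
    monoexponential dispersion kernel (1/tau) e^{-t/tau}."""
    t = curve.times
    v = curve(t + delay_s / 60.0)
    if tau_s > 0:
        a = 60.0 / tau_s
        v = a * expconv(t, v, a)
    return v


def tissue_concentration(params: KineticParams, cp_times: np.ndarray, cp_values: np.ndarray) -> np.ndarray:
    """Total tissue concentration C1 + C2 driven by the parent-plasma input.

    Closed form via the two-exponential impulse response; reduces exactly to
    the one-tissue solution when k3 = 0.
    """
    K1 = params.K1 / 100.0  # mL/100g/min -> 1/min per mL tissue
    k2, k3, k4 = params.k2, params.k3, params.k4
    if k3 == 0.0:
        return K1 * expconv(cp_times, cp_values, k2)
    s = k2 + k3 + k4
    disc = math.sqrt(max(s * s - 4.0 * k2 * k4, 0.0))
    th1 = 0.5 * (s + disc)
    th2 = 0.5 * (s - disc)
    c1 = K1 * (th1 - k3 - k4) / disc
    c2 = K1 * (k3 + k4 - th2) / disc
    return c1 * expconv(cp_times, cp_values, th1) + c2 * expconv(cp_times, cp_values, th2)


def frame_average(times_min: np.ndarray, values: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Interval mean of a fine-grid curve over each frame (trapezoid rule)."""
    cum = cumulative_trapezoid(values, times_min, initial=0.0)
    starts = schedule.starts / 60.0
    ends = schedule.ends / 60.0
    I0 = np.interp(starts, times_min, cum)
    I1 = np.interp(ends, times_min, cum)
    return (I1 - I0) / schedule.durations_min


def frame_weights(schedule: FrameSchedule, isotope: Isotope) -> np.ndarray:
    """Frame weights w_i proportional to Delta_i * exp(-lambda t_i), sum 1.

    Frame variance scales inversely with collected counts, hence with frame
    duration and the surviving (decaying) activity at the frame mid-time.
    """
    w = schedule.durations_min * np.exp(-isotope.lam * schedule.mids)
    return w / w.sum()


def _model_curve(params: KineticParams, spec: ModelSpec, input_function: InputFunction) -> np.ndarray:
    """Instantaneous C_PET(t) on the input grid."""
    cp = input_function.parent_plasma
    wb = input_function.whole_blood
    if spec.fit_delay_dispersion and (params.delay_s != 0.0 or params.tau_s != 0.0):
        cp_v = _dispersed_delayed(cp, params.delay_s, params.tau_s)
        wb_v = _dispersed_delayed(wb, params.delay_s, params.tau_s)
    else:
        cp_v, wb_v = cp.values, wb(cp.times)
    ct = tissue_concentration(params, cp.times, cp_v)
    return (1.0 - params.vB) * ct + params.vB * wb_v


def simulate_tissue_curve(
    params: KineticParams,
    spec: ModelSpec,
    input_function: InputFunction,
    schedule: FrameSchedule,
    fine: bool = False,
) -> np.ndarray:
    """Frame-averaged tissue TAC predicted by ``spec`` with ``params``.

    Rate constants not present in ``spec`` are forced to zero. With
    ``fine=True`` the instantaneous curve on the input grid is returned
    instead of frame averages.
    """
    zeroed = {}
    if spec.n_tissue == 1:
        zeroed.update(k3=0.0, k4=0.0)
        if not spec.reversible:
            zeroed.update(k2=0.0)
    elif not spec.reversible:
        zeroed.update(k4=0.0)
    if not spec.fit_vB:
        zeroed.update(vB=0.0)
    if zeroed:
        params = replace(params, **zeroed)
    t = input_function.parent_plasma.times
    if t[-1] * 60.0 < schedule.total_duration - 1e-6:
        raise ValueError("input function does not cover the frame schedule")
    fine_curve = _model_curve(params, spec, input_function)
    if fine:
        return fine_curve
    return frame_average(t, fine_curve, schedule)


# ---------------------------------------------------------------------------
# fitting


def _latin_starts(names: tuple[str, ...], n_starts: int) -> np.ndarray:
    """Deterministic Latin-square start grid over the parameter box."""
    p = len(names)
    lo = np.array([PARAM_BOUNDS[n][0] for n in names])
    hi = np.array([PARAM_BOUNDS[n][1] for n in names])
    starts = np.empty((n_starts, p))
    for i in range(n_starts):
        frac = (np.array([(i + j) % n_starts for j in range(p)]) + 0.5) / n_starts
        starts[i] = lo + frac * (hi - lo)
    return starts


def _vector_to_params(x: np.ndarray, names: tuple[str, ...]) -> KineticParams:
    kw = dict(zip(names, (float(v) for v in x)))
    return KineticParams(**{"K1": 0.0, **kw})


def fit_compartment_model(
    tac: np.ndarray,
    schedule: FrameSchedule,
    input_function: InputFunction,
    spec: ModelSpec,
    weights: np.ndarray | None = None,
    n_starts: int = 5,
    extra_start: KineticParams | None = None,
) -> FitResult:
    """Box-constrained weighted least-squares fit of one candidate model.

    Minimises ``sum_i w_i (tac_i - model_i)^2`` with ``n_starts``
    deterministic multi-starts over the parameter box; the lowest-WRSS
    solution wins (first start wins ties). ``extra_start`` adds one more
    start, typically the solution of the next-simpler nested model so the
    richer model can never end up above it. Standard errors come from the
    Gauss-Newton covariance scaled by the reduced chi-square.
    Non-convergence of every start is reported through ``converged=False``,
    never raised.
    """
    tac = np.asarray(tac, dtype=float)
    if tac.size != schedule.n_frames:
        raise ValueError("TAC length does not match the frame schedule")
    if weights is None:
        weights = np.full(tac.size, 1.0 / tac.size)
    weights = np.asarray(weights, dtype=float)
    sw = np.sqrt(weights)
    names = spec.param_names
    lo = np.array([PARAM_BOUNDS[n][0] for n in names])
    hi = np.array([PARAM_BOUNDS[n][1] for n in names])

    def resid(x: np.ndarray) -> np.ndarray:
        model = simulate_tissue_curve(_vector_to_params(x, names), spec, input_function, schedule)
        return sw * (model - tac)

    starts = list(_latin_starts(names, n_starts))
    if extra_start is not None:
        x_extra = np.clip([getattr(extra_start, n) for n in names], lo, hi)
        starts.append(np.asarray(x_extra, dtype=float))
    best = None
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:  # singular jacobian etc. on a bad start
            continue
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    if best is None:
        raise RuntimeError("all optimiser starts failed")

    params = _vector_to_params(best.x, names)
    wrss = float(2.0 * best.cost)
    n, p = tac.size, len(names)
    dof = max(n - p, 1)
    J = best.jac
    JtJ = J.T @ J
    try:
        cov = np.linalg.pinv(JtJ) * (wrss / dof)
        se_vec = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        se_vec = np.full(p, np.nan)
    se = {name: float(s) for name, s in zip(names, se_vec)}
    if wrss > 0:
        aic = n * math.log(wrss / n) + 2 * p
    else:
        aic = -math.inf
    return FitResult(
        model_id=spec.model_id,
        params=params,
        se=se,
        cov=cov,
        wrss=wrss,
        n_frames=n,
        n_params=p,
        aic=aic,
        converged=bool(best.status > 0),
        wrss_scale=float(np.sum(weights * tac**2)),
    )


def fit_candidate_models(
    tac: np.ndarray,
    schedule: FrameSchedule,
    input_function: InputFunction,
    weights: np.ndarray | None = None,
    n_starts: int = 5,
    models: dict[str, ModelSpec] = CANDIDATE_MODELS,
) -> dict[str, FitResult]:
    """Fit the nested candidate family, simplest first.

    Each richer model receives the preceding model's solution as an extra
    start, so the fitted WRSS is non-increasing along the nesting chain (a
    freed parameter can always sit at zero).
    """
    fits: dict[str, FitResult] = {}
    previous: KineticParams | None = None
    for model_id, spec in models.items():
        fits[model_id] = fit_compartment_model(tac, schedule, input_function, spec,
                                               weights=weights, n_starts=n_starts,
                                               extra_start=previous)
        previous = fits[model_id].params
    return fits


def fit_meyer_cbf(
    tac: np.ndarray,
    whole_blood: SampledCurve,
    schedule: FrameSchedule,
    weights: np.ndarray | None = None,
    n_starts: int = 5,
) -> CBFResult:
    """Meyer 5-parameter free-diffusion CBF fit of a [15O]water TAC.

    ``C_PET = (1-vB) CBF [e^{-k2' t} (x) Ca_d] + vB Ca_d`` where ``Ca_d`` is
    the arterial curve shifted by a free delay and dispersed by a
    monoexponential kernel of free time constant tau. Water is freely
    diffusible, so a reversible one-tissue structure with K1 = CBF applies.
    """
    spec = ModelSpec(n_tissue=1, reversible=True, fit_vB=True, fit_delay_dispersion=True)
    input_function = InputFunction(
        whole_blood=whole_blood, parent_plasma=whole_blood, pob=1.0
    )
    fit = fit_compartment_model(tac, schedule, input_function, spec,
                                weights=weights, n_starts=n_starts)
    return CBFResult(
        CBF=fit.params.K1,
        k2p=fit.params.k2,
        vB=fit.params.vB,
        delay_s=fit.params.delay_s,
        tau_s=fit.params.tau_s,
        se={"CBF": fit.se["K1"], "k2p": fit.se["k2"], "vB": fit.se["vB"],
            "delay_s": fit.se["delay_s"], "tau_s": fit.se["tau_s"]},
        wrss=fit.wrss,
        converged=fit.converged,
    )
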