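"""Synthetic test-retest PET studies with the statistical structure the
analysis assumes.

The generator emulates, per subject and session, a paired [15O]water +
[13N]ammonia scanning session: a gamma-variate arterial bolus with a slow
recirculation tail recorded by a continuous detector (cross-calibration
scale factor, transit delay), manual whole-blood and plasma samples, a
biexponentially declining parent fraction (below 50% by the first 4-min
sample), region TACs generated by the compartment models with a
blood-volume term, and frame noise whose variance follows the
1/(Delta_i e^{-lambda t_i}) counting law.

Default truth values are anchored to the study population this package
analyses: grey-matter CBF ~37.6, ammonia K1 ~20.1 mL/100 g/min, k2
~0.0069 /min, plasma-over-blood 1.14 +/- 0.03, blood ammonia 24.5 +/- 5.7
umol/L. Bolus shape and noise scale are generator choices documented in the
methods note. Same seed => bit-identical study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .blood import InputFunction, ParentFractionFit, SampledCurve, build_parent_plasma_input
from .frames import AMMONIA_FRAMING, WATER_FRAMING, FrameSchedule, Isotope, N13, O15, make_schedule
from .kinetics import KineticParams, ModelSpec, CANDIDATE_MODELS, simulate_tissue_curve

__all__ = [
    "RegionTruth",
    "SyntheticConfig",
    "ScanData",
    "SubjectSession",
    "SyntheticStudy",
    "NoisyTAC",
    "generate_input_function",
    "add_frame_noise",
    "generate_study",
    "DEFAULT_REGIONS",
]

#: Manual arterial sample times for the ammonia scan, minutes post-injection.
AMMONIA_MANUAL_TIMES_MIN = (4.0, 6.0, 8.0, 12.0, 20.0, 30.0)
#: Manual sample times for the 5-min water scan (calibration only).
WATER_MANUAL_TIMES_MIN = (2.0, 3.5, 5.0)


@dataclass(frozen=True)
class RegionTruth:
    """Population truth for one region: means and between-subject sds."""

    cbf: float
    cbf_sd: float
    K1: float
    K1_sd: float
    k2: float
    k2_sd: float
    k3: float = 0.0
    k3_sd: float = 0.0
    vB: float = 0.04


#: Regional truth anchored to the test-session population values
#: (CBF/K1 in mL/100 g/min, k2/k3 in 1/min).
DEFAULT_REGIONS: dict[str, RegionTruth] = {
    "grey_matter": RegionTruth(37.6, 4.8, 20.1, 1.5, 0.0069, 0.0029, 0.0031, 0.0045, 0.05),
    "white_matter": RegionTruth(25.8, 3.4, 14.5, 1.2, 0.0059, 0.0027, 0.0139, 0.0177, 0.03),
    "hippocampus_l": RegionTruth(32.1, 3.7, 18.9, 2.4, 0.0122, 0.0061, 0.0532, 0.0261, 0.04),
    "thalamus_l": RegionTruth(43.9, 5.5, 22.5, 2.1, 0.0089, 0.0030, 0.0241, 0.0214, 0.05),
    "cerebellum_l": RegionTruth(41.7, 6.8, 22.4, 2.0, 0.0061, 0.0027, 0.0056, 0.0126, 0.05),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the study generator; defaults define the study conditions."""

    seed: int = 0
    n_subjects: int = 8
    regions: dict[str, RegionTruth] = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    #: generating model for the ammonia TACs ("1tcm_rev" or "2tcm_irr")
    generating_model: str = "1tcm_rev"
    ammonia_framing: tuple = tuple(AMMONIA_FRAMING)
    water_framing: tuple = tuple(WATER_FRAMING)
    # arterial bolus (shape choices; see methods note)
    bolus_amplitude: float = 100.0  # kBq/mL at the peak
    bolus_onset_s: float = 30.0
    bolus_shape: float = 3.0        # gamma-variate exponent
    bolus_peak_width_s: float = 15.0
    tail_fraction: float = 0.15     # recirculation plateau as a fraction of peak
    tail_half_life_min: float = 10.0
    # blood measurement chain
    detector_scale_mean: float = 0.90
    detector_scale_sd: float = 0.05
    true_delay_mean_s: float = 6.0
    true_delay_sd_s: float = 2.0
    continuous_noise_frac: float = 0.002   # of peak, on the 1 s record
    manual_noise_frac: float = 0.02
    continuous_duration_ammonia_min: float = 15.0
    # parent fraction truth (fast share under 50% by 4 min)
    pf_A: float = 0.65
    pf_A_sd: float = 0.05
    pf_alpha: float = 0.5
    pf_alpha_sd: float = 0.1
    pf_beta: float = 0.04
    pf_beta_sd: float = 0.01
    pf_noise_sd: float = 0.02
    # plasma-over-blood and physiology
    pob_mean: float = 1.14
    pob_sd: float = 0.03
    baseline_ammonia_mean: float = 24.5   # umol/L
    baseline_ammonia_sd: float = 5.7
    water_dose_MBq: tuple[float, float] = (841.0, 126.0)
    ammonia_dose_MBq: tuple[float, float] = (537.0, 7.0)
    # water-model extras
    water_partition: float = 0.9    # mL/mL, sets k2' = CBF/100/partition
    water_dispersion_tau_s: float = 4.0
    # variability and noise
    between_session_cv: float = 0.05
    noise_scale: float = 0.05
    #: if set, ammonia K1 is generated as this extraction fraction times the
    #: session CBF instead of being drawn independently
    k1_ef_coupling: float | None = None

    @property
    def water_schedule(self) -> FrameSchedule:
        return make_schedule(list(self.water_framing))

    @property
    def ammonia_schedule(self) -> FrameSchedule:
        return make_schedule(list(self.ammonia_framing))


@dataclass
class ScanData:
    """Everything the pipeline reads for one scan of one session."""

    isotope: Isotope
    schedule: FrameSchedule
    continuous_blood: SampledCurve
    manual_blood: SampledCurve
    manual_plasma: SampledCurve | None
    parent_fraction_samples: np.ndarray | None  # columns (time_min, fraction)
    tacs: dict[str, np.ndarray]


@dataclass
class SubjectSession:
    subject: str
    session: str
    baseline_ammonia: float   # umol/L
    injected_water_MBq: float
    injected_ammonia_MBq: float
    water: ScanData
    ammonia: ScanData


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    sessions: dict[tuple[str, str], SubjectSession]
    truth: pd.DataFrame  # long: subject, session, region, parameter, value


class NoisyTAC(NamedTuple):
    values: np.ndarray
    n_clipped: int


def _rng(config_seed: int, *stream: int) -> np.random.Generator:
    """Stable per-stream generator: adding subjects never perturbs others."""
    return np.random.default_rng(np.random.SeedSequence((config_seed, *stream)))


def _gamma_variate(t_min: np.ndarray, amp: float, onset_s: float, shape: float, peak_width_s: float) -> np.ndarray:
    tp = peak_width_s / 60.0
    x = (t_min - onset_s / 60.0) / tp
    out = np.zeros_like(t_min)
    pos = x > 0
    out[pos] = amp * np.power(x[pos], shape) * np.exp(shape * (1.0 - x[pos]))
    return out


def arterial_truth(config: SyntheticConfig, t_min: np.ndarray) -> np.ndarray:
    """Decay-corrected whole-blood concentration: bolus + recirculation tail."""
    bolus = _gamma_variate(t_min, config.bolus_amplitude, config.bolus_onset_s,
                           config.bolus_shape, config.bolus_peak_width_s)
    if config.tail_fraction <= 0:
        return bolus
    x = t_min - config.bolus_onset_s / 60.0
    rise = -np.expm1(-np.maximum(x, 0.0) / 0.5)  # ~30 s rise to the plateau
    decay = np.exp(-math.log(2.0) / config.tail_half_life_min * np.maximum(x, 0.0))
    return bolus + config.tail_fraction * config.bolus_amplitude * rise * decay


def generate_input_function(
    config: SyntheticConfig,
    isotope: Isotope,
    seed_stream: tuple[int, ...] = (0,),
) -> dict:
    """One scan's blood data: truth curve, detector record, manual samples.

    The continuous record is the truth shifted later by the transit delay,
    scaled by the detector cross-calibration factor and lightly noised; it
    stops at 15 min for ammonia (manual samples carry the tail to 30 min) and
    covers the full 5-min water scan. Parent-fraction samples (ammonia only)
    are the biexponential truth plus N(0, 0.02) noise clipped to [0, 1].
    """
    rng = _rng(config.seed, *seed_stream)
    is_water = isotope.name == O15.name
    scan_min = config.water_schedule.total_duration / 60.0 if is_water \
        else config.ammonia_schedule.total_duration / 60.0
    dt = 1.0 / 60.0
    t = np.arange(0.0, scan_min + 0.5 * dt, dt)
    wb_true = arterial_truth(config, t)

    delay_s = float(np.clip(rng.normal(config.true_delay_mean_s, config.true_delay_sd_s), 0.0, 12.0))
    scale = float(np.clip(rng.normal(config.detector_scale_mean, config.detector_scale_sd), 0.5, 1.5))
    cont_end = scan_min if is_water else min(config.continuous_duration_ammonia_min, scan_min)
    t_cont = t[t <= cont_end + 1e-9]
    truth_curve = SampledCurve(t, wb_true)
    delayed = truth_curve(t_cont - delay_s / 60.0)
    noise = rng.normal(0.0, config.continuous_noise_frac * wb_true.max(), t_cont.size)
    cont_values = np.maximum(delayed * scale + noise, 0.0)

    manual_times = np.asarray(WATER_MANUAL_TIMES_MIN if is_water else AMMONIA_MANUAL_TIMES_MIN)
    manual_times = manual_times[manual_times <= scan_min + 1e-9]
    manual_true = truth_curve(manual_times - delay_s / 60.0)
    manual_wb = manual_true * (1.0 + rng.normal(0.0, config.manual_noise_frac, manual_times.size))

    out = {
        "truth_whole_blood": truth_curve,
        "true_delay_s": delay_s,
        "detector_scale": scale,
        "continuous": SampledCurve(t_cont, cont_values),
        "manual_blood": SampledCurve(manual_times, manual_wb),
        "manual_plasma": None,
        "parent_fraction_samples": None,
        "pf_truth": None,
        "pob_truth": None,
    }
    if not is_water:
        pob = float(np.clip(rng.normal(config.pob_mean, config.pob_sd), 0.9, 1.4))
        A = float(np.clip(rng.normal(config.pf_A, config.pf_A_sd), 0.4, 0.85))
        alpha = float(max(rng.normal(config.pf_alpha, config.pf_alpha_sd), 0.15))
        beta = float(max(rng.normal(config.pf_beta, config.pf_beta_sd), 0.005))
        if alpha < beta:
            alpha, beta = beta, alpha
        pf = ParentFractionFit(A=A, alpha=alpha, beta=beta)
        manual_plasma = pob * manual_true * (1.0 + rng.normal(0.0, config.manual_noise_frac, manual_times.size))
        pf_samples = np.column_stack([
            manual_times,
            np.clip(pf(manual_times) + rng.normal(0.0, config.pf_noise_sd, manual_times.size), 0.0, 1.0),
        ])
        out.update(
            manual_plasma=SampledCurve(manual_times, manual_plasma),
            parent_fraction_samples=pf_samples,
            pf_truth=pf,
            pob_truth=pob,
        )
    return out


def add_frame_noise(
    tac: np.ndarray,
    schedule: FrameSchedule,
    isotope: Isotope,
    noise_scale: float,
    rng: np.random.Generator,
) -> NoisyTAC:
    """Gaussian frame noise with the PET counting variance law.

    ``sd_i = noise_scale * sqrt(Cbar / (Delta_i e^{-lambda t_i}))`` with
    ``Cbar`` the mean TAC value, so variance is inversely proportional to
    frame duration times the decay factor. Negative results are clipped to 0
    and the clip count reported.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")
    tac = np.asarray(tac, dtype=float)
    if noise_scale == 0:
        return NoisyTAC(tac.copy(), 0)
    cbar = float(np.mean(tac))
    sd = noise_scale * np.sqrt(max(cbar, 0.0) / (schedule.durations_min * np.exp(-isotope.lam * schedule.mids)))
    noisy = tac + rng.normal(0.0, 1.0, tac.size) * sd
    n_clipped = int(np.sum(noisy < 0))
    return NoisyTAC(np.maximum(noisy, 0.0), n_clipped)


def _session_value(rng: np.random.Generator, subject_value: float, cv: float, floor: float) -> float:
    return float(max(subject_value * (1.0 + rng.normal(0.0, cv)), floor))


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """A full n_subjects x 2-session test-retest study with a truth ledger.

    Subject-level kinetic parameters are drawn from the configured
    between-subject distributions once per subject; session values add
    multiplicative between-session jitter. Every generated quantity is
    recorded in the long-format ``truth`` table.
    """
    water_sched = config.water_schedule
    ammonia_sched = config.ammonia_schedule
    gen_spec = CANDIDATE_MODELS[config.generating_model]
    meyer_spec = ModelSpec(1, reversible=True, fit_vB=True, fit_delay_dispersion=True)

    sessions: dict[tuple[str, str], SubjectSession] = {}
    truth_rows: list[dict] = []

    def record(subject, session, region, parameter, value):
        truth_rows.append(dict(subject=subject, session=session, region=region,
                               parameter=parameter, value=float(value)))

    for si in range(config.n_subjects):
        subject = f"sub{si + 1:02d}"
        srng = _rng(config.seed, si, 0, 0)
        subj_params: dict[str, dict[str, float]] = {}
        for region, rt in config.regions.items():
            subj_params[region] = {
                "cbf": max(srng.normal(rt.cbf, rt.cbf_sd), 5.0),
                "K1": max(srng.normal(rt.K1, rt.K1_sd), 1.0),
                "k2": max(srng.normal(rt.k2, rt.k2_sd), 5e-4),
                "k3": max(srng.normal(rt.k3, rt.k3_sd), 0.0),
                "vB": rt.vB,
            }
        baseline_a = float(max(_rng(config.seed, si, 0, 1).normal(
            config.baseline_ammonia_mean, config.baseline_ammonia_sd), 5.0))

        for se, session in enumerate(("S1", "S2")):
            jrng = _rng(config.seed, si, se + 1, 2)
            water_blood = generate_input_function(config, O15, (si, se + 1, 3))
            ammonia_blood = generate_input_function(config, N13, (si, se + 1, 4))
            nrng = _rng(config.seed, si, se + 1, 5)

            # session-level truth: subject values plus between-session jitter
            sess_params: dict[str, dict[str, float]] = {}
            for region, p in subj_params.items():
                cbf = _session_value(jrng, p["cbf"], config.between_session_cv, 5.0)
                if config.k1_ef_coupling is not None:
                    K1 = config.k1_ef_coupling * cbf
                else:
                    K1 = _session_value(jrng, p["K1"], config.between_session_cv, 1.0)
                sess_params[region] = {
                    "cbf": cbf,
                    "K1": K1,
                    "k2": _session_value(jrng, p["k2"], config.between_session_cv, 5e-4),
                    "k3": _session_value(jrng, p["k3"], config.between_session_cv, 0.0)
                    if gen_spec.n_tissue == 2 else 0.0,
                    "vB": p["vB"],
                }

            # --- water scan: Meyer forward model on the calibrated truth record
            wtruth = water_blood["truth_whole_blood"]
            # what a perfectly calibrated pipeline would see (delayed record, true scale undone)
            t_w = wtruth.times
            wb_record = SampledCurve(t_w, wtruth(t_w - water_blood["true_delay_s"] / 60.0))
            water_input = InputFunction(whole_blood=wb_record, parent_plasma=wb_record, pob=1.0)
            water_tacs: dict[str, np.ndarray] = {}
            for region, p in sess_params.items():
                cbf = p["cbf"]
                k2p = cbf / 100.0 / config.water_partition
                params = KineticParams(K1=cbf, k2=k2p, vB=p["vB"],
                                       delay_s=water_blood["true_delay_s"],
                                       tau_s=config.water_dispersion_tau_s)
                clean = simulate_tissue_curve(params, meyer_spec, water_input, water_sched)
                noisy = add_frame_noise(clean, water_sched, O15, config.noise_scale, nrng)
                water_tacs[region] = noisy.values
                record(subject, session, region, "CBF", cbf)
                record(subject, session, region, "water_k2p", k2p)
                record(subject, session, region, "water_vB", p["vB"])

            # --- ammonia scan: compartment model on the parent-plasma truth
            atruth = ammonia_blood["truth_whole_blood"]
            pf = ammonia_blood["pf_truth"]
            pob = ammonia_blood["pob_truth"]
            ammonia_input = build_parent_plasma_input(atruth, pob, pf, delay_s=0.0)
            ammonia_tacs: dict[str, np.ndarray] = {}
            for region, p in sess_params.items():
                params = KineticParams(K1=p["K1"], k2=p["k2"], k3=p["k3"], vB=p["vB"])
                clean = simulate_tissue_curve(params, gen_spec, ammonia_input, ammonia_sched)
                noisy = add_frame_noise(clean, ammonia_sched, N13, config.noise_scale, nrng)
                ammonia_tacs[region] = noisy.values
                for name in ("K1", "k2", "k3", "vB"):
                    record(subject, session, region, name, p[name])

            drng = _rng(config.seed, si, se + 1, 6)
            record(subject, session, "", "baseline_ammonia", baseline_a)
            record(subject, session, "", "pob", pob)
            record(subject, session, "", "pf_A", pf.A)
            record(subject, session, "", "pf_alpha", pf.alpha)
            record(subject, session, "", "pf_beta", pf.beta)
            record(subject, session, "", "water_delay_s", water_blood["true_delay_s"])
            record(subject, session, "", "ammonia_delay_s", ammonia_blood["true_delay_s"])

            sessions[(subject, session)] = SubjectSession(
                subject=subject,
                session=session,
                baseline_ammonia=baseline_a,
                injected_water_MBq=float(drng.normal(*config.water_dose_MBq)),
                injected_ammonia_MBq=float(drng.normal(*config.ammonia_dose_MBq)),
                water=ScanData(
                    isotope=O15, schedule=water_sched,
                    continuous_blood=water_blood["continuous"],
                    manual_blood=water_blood["manual_blood"],
                    manual_plasma=None, parent_fraction_samples=None,
                    tacs=water_tacs,
                ),
                ammonia=ScanData(
                    isotope=N13, schedule=ammonia_sched,
                    continuous_blood=ammonia_blood["continuous"],
                    manual_blood=ammonia_blood["manual_blood"],
                    manual_plasma=ammonia_blood["manual_plasma"],
                    parent_fraction_samples=ammonia_blood["parent_fraction_samples"],
                    tacs=ammonia_tacs,
                ),
            )

    return SyntheticStudy(config=config, sessions=sessions, truth=pd.DataFrame(truth_rows))
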