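"""Per-session analysis and study-level test-retest reporting.

``run_session`` processes one paired water + ammonia session end to end:
blood calibration, metabolite correction, delay matching, the Meyer CBF
fit, the four candidate ammonia fits with AIC selection, Patlak K_met, the
derived macroparameters and the k3 identifiability test, one row per
region. ``run_study`` repeats that over every subject and session and
produces the repeatability tables and the CBF-vs-K1 correlation report.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import blood as bl
from . import derived, graphical, modelsel
from .blood import InputFunction, ParentFractionFit, SampledCurve
from .frames import N13, O15
from .kinetics import (
    fit_candidate_models,
    fit_meyer_cbf,
    frame_weights,
)
from .repeatability import icc_threshold, repeatability_table
from .synthetic import ScanData, SubjectSession, SyntheticStudy

__all__ = ["AnalysisOptions", "process_ammonia_blood", "run_session", "run_study",
           "zero_intercept_fit"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisOptions:
    """Settings of the per-session analysis."""

    tstar: float = 20.0            # Patlak start time, min
    alpha: float = 0.05            # identifiability / ICC significance level
    weighted: bool = True          # frame-duration x decay weighting
    reference_region: str = "grey_matter"  # delay-matching reference TAC
    pob_fallback: float = 1.14     # population plasma-over-blood if no samples
    n_starts: int = 5


def process_ammonia_blood(
    scan: ScanData,
    options: AnalysisOptions = AnalysisOptions(),
) -> tuple[InputFunction, dict]:
    """Whole-blood calibration, metabolite correction and delay matching.

    Returns the assembled :class:`InputFunction` and a diagnostics dict
    (pob, parent-fraction fit, estimated delay, calibration scale inputs).
    """
    scan_end = scan.schedule.total_duration / 60.0
    wb = bl.calibrate_continuous(scan.continuous_blood, scan.manual_blood, scan_end)

    if scan.manual_plasma is not None:
        pairs = list(zip(scan.manual_plasma.values, scan.manual_blood.values))
        pob = bl.plasma_over_blood(pairs)
    else:
        pob = options.pob_fallback
        log.warning("no manual plasma samples; using population pob %.2f", pob)

    if scan.parent_fraction_samples is not None:
        pf = bl.fit_parent_fraction(scan.parent_fraction_samples)
    else:
        pf = ParentFractionFit(A=0.0, alpha=0.0, beta=0.0)  # f(t) = 1

    region = options.reference_region if options.reference_region in scan.tacs \
        else next(iter(scan.tacs))
    ref = SampledCurve(scan.schedule.mids, scan.tacs[region])
    delay = bl.estimate_delay(wb, ref)
    input_function = bl.build_parent_plasma_input(wb, pob, pf, delay)
    return input_function, {"pob": pob, "parent_fraction": pf, "delay_s": delay,
                            "reference_region": region}


def run_session(
    study: SyntheticStudy,
    subject: str,
    session: str,
    options: AnalysisOptions = AnalysisOptions(),
) -> pd.DataFrame:
    """Full kinetic analysis of one subject-session; one row per region.

    A failing region is flagged (``converged=False``) and the run continues.
    """
    ss: SubjectSession = study.sessions[(subject, session)]
    water, ammonia = ss.water, ss.ammonia
    w_weights = frame_weights(water.schedule, O15) if options.weighted else None
    a_weights = frame_weights(ammonia.schedule, N13) if options.weighted else None

    water_end = water.schedule.total_duration / 60.0
    water_wb = bl.calibrate_continuous(water.continuous_blood, water.manual_blood, water_end)
    ammonia_input, blood_diag = process_ammonia_blood(ammonia, options)

    rows = []
    for region in ammonia.tacs:
        row: dict = {"subject": subject, "session": session, "region": region}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row.update(_analyse_region(
                    region, water, water_wb, w_weights,
                    ammonia, ammonia_input, a_weights, ss, options))
            row.setdefault("converged", True)
        except Exception as exc:  # a degenerate region must not kill the session
            log.warning("region %s failed: %s", region, exc)
            row["converged"] = False
            row["error"] = str(exc)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["blood"] = blood_diag
    return df


def _analyse_region(region, water, water_wb, w_weights, ammonia, ammonia_input,
                    a_weights, ss: SubjectSession, options: AnalysisOptions) -> dict:
    out: dict = {}
    converged = True

    if region in water.tacs:
        cbf_fit = fit_meyer_cbf(water.tacs[region], water_wb, water.schedule,
                                weights=w_weights, n_starts=options.n_starts)
        out.update(CBF=cbf_fit.CBF, CBF_se=cbf_fit.se["CBF"], water_k2p=cbf_fit.k2p,
                   water_vB=cbf_fit.vB, water_delay_s=cbf_fit.delay_s,
                   water_tau_s=cbf_fit.tau_s)
        converged &= cbf_fit.converged
    else:
        out.update(CBF=math.nan)

    tac = ammonia.tacs[region]
    fits = fit_candidate_models(tac, ammonia.schedule, ammonia_input,
                                weights=a_weights, n_starts=options.n_starts)
    comparison = modelsel.select_model(fits.values())
    out["selected_model"] = comparison.selected
    out["delta_aic_selected"] = 0.0

    f2 = fits["2tcm_irr"]
    out.update(K1_2tcm=f2.params.K1, k2_2tcm=f2.params.k2, k3_2tcm=f2.params.k3,
               vB_2tcm=f2.params.vB, K1_2tcm_se=f2.se["K1"], k3_2tcm_se=f2.se["k3"])
    ident = modelsel.identifiability_test(
        f2.params.k3, max(f2.se["k3"], 1e-300), df=f2.n_frames - f2.n_params,
        alpha=options.alpha, parameter="k3")
    out.update(k3_t=ident.t, k3_p=ident.p_one_sided, k3_significant=ident.significant)

    f1 = fits["1tcm_rev"]
    out.update(K1_1tcm=f1.params.K1, k2_1tcm=f1.params.k2, vB_1tcm=f1.params.vB,
               K1_1tcm_se=f1.se["K1"], k2_1tcm_se=f1.se["k2"])
    if f1.params.k2 > 0:
        out["VT"] = derived.volume_of_distribution(f1.params.K1, f1.params.k2)
        out["washout_half_life_min"] = derived.washout_half_life(f1.params.k2)
    converged &= all(f.converged for f in fits.values())

    pat = graphical.patlak(tac, ammonia.schedule, ammonia_input.parent_plasma,
                           tstar=options.tstar)
    out.update(Kmet=pat.Kmet, patlak_intercept=pat.intercept, patlak_r2=pat.r2)

    cbf = out.get("CBF", math.nan)
    if np.isfinite(cbf) and cbf > 0:
        out["PS_BBB"] = derived.ps_product(cbf, f2.params.K1) \
            if f2.params.K1 < cbf else math.inf
        out["EF"] = derived.extraction_fraction(f2.params.K1, cbf)
        out["PS_met"] = derived.ps_product(cbf, pat.Kmet) \
            if 0 <= pat.Kmet < cbf else math.nan
    out["Flux_met"] = derived.flux_met(max(pat.Kmet, 0.0), ss.baseline_ammonia)
    out["converged"] = converged
    return out


def zero_intercept_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares line through the origin; returns (slope, r2 about the mean)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all x are zero")
    slope = float(np.sum(x * y)) / sxx
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope, r2


#: Parameters carried into the repeatability tables.
REPEAT_PARAMETERS = ("CBF", "K1_1tcm", "k2_1tcm", "K1_2tcm", "k2_2tcm", "k3_2tcm",
                     "Kmet", "VT", "PS_BBB", "EF", "Flux_met")


def run_study(
    study: SyntheticStudy,
    options: AnalysisOptions = AnalysisOptions(),
) -> dict[str, pd.DataFrame]:
    """Analyse every complete subject (both sessions) and summarise.

    Returns a dict of DataFrames: ``sessions`` (per-region fits),
    ``estimates`` (long format), ``repeatability`` (ICC/VAR/AbsVAR per
    region x parameter, with the ICC significance threshold), ``cbf_k1``
    (across-region zero-intercept K1-vs-CBF fits per subject x session) and
    ``model_selection`` (candidate counts).
    """
    subjects = sorted({s for s, _ in study.sessions})
    complete = [s for s in subjects
                if (s, "S1") in study.sessions and (s, "S2") in study.sessions]
    dropped = set(subjects) - set(complete)
    if dropped:
        log.warning("dropping single-session subjects: %s", sorted(dropped))
    if len(complete) < 2:
        raise ValueError("need both sessions for at least 2 subjects")

    session_tables = []
    for subject in complete:
        for session in ("S1", "S2"):
            session_tables.append(run_session(study, subject, session, options))
    sessions_df = pd.concat(session_tables, ignore_index=True)

    melted = sessions_df.melt(
        id_vars=["subject", "session", "region"],
        value_vars=[p for p in REPEAT_PARAMETERS if p in sessions_df.columns],
        var_name="parameter", value_name="value").dropna(subset=["value"])
    melted = melted[np.isfinite(melted["value"])]

    repeat = repeatability_table(melted)
    if not repeat.empty:
        repeat["icc_threshold"] = repeat["n_subjects"].map(
            lambda n: icc_threshold(int(n), options.alpha))
        repeat["icc_significant"] = repeat["icc"] > repeat["icc_threshold"]
        repeat["low_n"] = repeat["n_subjects"] < 4

    corr_rows = []
    for (subject, session), grp in sessions_df.groupby(["subject", "session"]):
        for k1_col in ("K1_1tcm", "K1_2tcm", "Kmet"):
            if k1_col not in grp or "CBF" not in grp:
                continue
            sub = grp[["CBF", k1_col]].dropna()
            sub = sub[np.isfinite(sub).all(axis=1)]
            if len(sub) < 2:
                continue
            slope, r2 = zero_intercept_fit(sub["CBF"], sub[k1_col])
            corr_rows.append({"subject": subject, "session": session,
                              "parameter": k1_col, "slope": slope, "r2": r2,
                              "n_regions": len(sub)})
    cbf_k1 = pd.DataFrame(corr_rows)

    counts = sessions_df.groupby("selected_model").size().rename("n_tacs").reset_index() \
        if "selected_model" in sessions_df else pd.DataFrame()

    return {"sessions": sessions_df, "estimates": melted, "repeatability": repeat,
            "cbf_k1": cbf_k1, "model_selection": counts}
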