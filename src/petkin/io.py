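"""Tabular text I/O: TAC files, blood files, parent fractions, study trees.

Formats (all plain CSV, times in the units named by the column header):

* TAC files: ``frame_start_s, frame_duration_s, region, activity_kBq_per_mL``
  (one row per frame per region).
* Blood files: ``time_s, activity_kBq_per_mL, source`` with source one of
  ``continuous``, ``manual_wb``, ``manual_plasma``.
* Parent-fraction files: ``time_min, parent_fraction``.

Study trees written by :func:`write_study` round-trip losslessly through
:func:`read_study`.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .blood import SampledCurve
from .frames import FrameSchedule, Isotope, N13, O15
from .synthetic import ScanData, SubjectSession, SyntheticConfig, SyntheticStudy

__all__ = [
    "write_tacs",
    "read_tacs",
    "write_blood",
    "read_blood",
    "write_parent_fraction",
    "read_parent_fraction",
    "write_study",
    "read_study",
    "write_table",
]

_FLOAT_FMT = "%.17g"  # lossless float round-trip


def write_tacs(path: Path | str, schedule: FrameSchedule, tacs: dict[str, np.ndarray]) -> None:
    rows = []
    for region, values in tacs.items():
        for start, dur, v in zip(schedule.starts, schedule.durations, values):
            rows.append((start, dur, region, v))
    df = pd.DataFrame(rows, columns=["frame_start_s", "frame_duration_s", "region",
                                     "activity_kBq_per_mL"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_tacs(path: Path | str) -> tuple[FrameSchedule, dict[str, np.ndarray]]:
    df = pd.read_csv(path, float_precision="round_trip")
    first = df[df["region"] == df["region"].iloc[0]]
    schedule = FrameSchedule(first["frame_start_s"].to_numpy(),
                             first["frame_duration_s"].to_numpy())
    tacs = {
        str(region): grp["activity_kBq_per_mL"].to_numpy()
        for region, grp in df.groupby("region", sort=False)
    }
    return schedule, tacs


def write_blood(
    path: Path | str,
    continuous: SampledCurve,
    manual_wb: SampledCurve,
    manual_plasma: SampledCurve | None = None,
) -> None:
    parts = [
        pd.DataFrame({"time_s": continuous.times * 60.0,
                      "activity_kBq_per_mL": continuous.values, "source": "continuous"}),
        pd.DataFrame({"time_s": manual_wb.times * 60.0,
                      "activity_kBq_per_mL": manual_wb.values, "source": "manual_wb"}),
    ]
    if manual_plasma is not None:
        parts.append(pd.DataFrame({"time_s": manual_plasma.times * 60.0,
                                   "activity_kBq_per_mL": manual_plasma.values,
                                   "source": "manual_plasma"}))
    pd.concat(parts).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_blood(path: Path | str) -> dict[str, SampledCurve | None]:
    df = pd.read_csv(path, float_precision="round_trip")
    out: dict[str, SampledCurve | None] = {"continuous": None, "manual_wb": None,
                                           "manual_plasma": None}
    for source, grp in df.groupby("source"):
        out[str(source)] = SampledCurve(grp["time_s"].to_numpy() / 60.0,
                                        grp["activity_kBq_per_mL"].to_numpy())
    return out


def write_parent_fraction(path: Path | str, samples: np.ndarray) -> None:
    pd.DataFrame(samples, columns=["time_min", "parent_fraction"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


def read_parent_fraction(path: Path | str) -> np.ndarray:
    df = pd.read_csv(path, float_precision="round_trip")
    return df[["time_min", "parent_fraction"]].to_numpy()


def _config_dict(config: SyntheticConfig) -> dict:
    d = {}
    for key, value in vars(config).items():
        if key == "regions":
            d["regions"] = {name: vars(rt).copy() for name, rt in value.items()}
        elif isinstance(value, tuple):
            d[key] = list(list(v) if isinstance(v, tuple) else v for v in value) \
                if key.endswith("framing") else list(value)
        else:
            d[key] = value
    return d


def config_hash(config: SyntheticConfig) -> str:
    payload = yaml.safe_dump(_config_dict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_study(study: SyntheticStudy, outdir: Path | str) -> Path:
    """Write a full synthetic study tree (config, truth ledger, per-session files)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(_config_dict(study.config), fh, sort_keys=True)
    study.truth.to_csv(outdir / "truth.csv", index=False, float_format=_FLOAT_FMT)
    for (subject, session), ss in sorted(study.sessions.items()):
        d = outdir / subject / session
        d.mkdir(parents=True, exist_ok=True)
        for scan_name in ("water", "ammonia"):
            scan: ScanData = getattr(ss, scan_name)
            write_tacs(d / f"{scan_name}_tac.csv", scan.schedule, scan.tacs)
            write_blood(d / f"{scan_name}_blood.csv", scan.continuous_blood,
                        scan.manual_blood, scan.manual_plasma)
            if scan.parent_fraction_samples is not None:
                write_parent_fraction(d / f"{scan_name}_parent_fraction.csv",
                                      scan.parent_fraction_samples)
        with open(d / "meta.yaml", "w") as fh:
            yaml.safe_dump({
                "subject": subject,
                "session": session,
                "baseline_ammonia_umol_L": ss.baseline_ammonia,
                "injected_water_MBq": ss.injected_water_MBq,
                "injected_ammonia_MBq": ss.injected_ammonia_MBq,
            }, fh, sort_keys=True)
    return outdir


def _read_scan(d: Path, scan_name: str, isotope: Isotope) -> ScanData:
    schedule, tacs = read_tacs(d / f"{scan_name}_tac.csv")
    blood = read_blood(d / f"{scan_name}_blood.csv")
    pf_path = d / f"{scan_name}_parent_fraction.csv"
    pf = read_parent_fraction(pf_path) if pf_path.exists() else None
    return ScanData(
        isotope=isotope,
        schedule=schedule,
        continuous_blood=blood["continuous"],
        manual_blood=blood["manual_wb"],
        manual_plasma=blood["manual_plasma"],
        parent_fraction_samples=pf,
        tacs=tacs,
    )


def read_study(indir: Path | str) -> SyntheticStudy:
    """Read a study tree written by :func:`write_study`."""
    indir = Path(indir)
    with open(indir / "config.yaml") as fh:
        raw = yaml.safe_load(fh)
    from .synthetic import RegionTruth  # local to avoid cycle at import time
    raw["regions"] = {name: RegionTruth(**rt) for name, rt in raw["regions"].items()}
    for key in ("ammonia_framing", "water_framing"):
        raw[key] = tuple(tuple(pair) for pair in raw[key])
    for key in ("water_dose_MBq", "ammonia_dose_MBq"):
        raw[key] = tuple(raw[key])
    config = SyntheticConfig(**raw)
    truth_path = indir / "truth.csv"
    truth = pd.read_csv(truth_path, keep_default_na=False, float_precision="round_trip") if truth_path.exists() else pd.DataFrame()
    sessions: dict[tuple[str, str], SubjectSession] = {}
    for meta_path in sorted(indir.glob("*/*/meta.yaml")):
        d = meta_path.parent
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh)
        sessions[(meta["subject"], meta["session"])] = SubjectSession(
            subject=meta["subject"],
            session=meta["session"],
            baseline_ammonia=meta["baseline_ammonia_umol_L"],
            injected_water_MBq=meta["injected_water_MBq"],
            injected_ammonia_MBq=meta["injected_ammonia_MBq"],
            water=_read_scan(d, "water", O15),
            ammonia=_read_scan(d, "ammonia", N13),
        )
    return SyntheticStudy(config=config, sessions=sessions, truth=truth)


def write_table(df: pd.DataFrame, path: Path | str, **metadata) -> None:
    """Write a results table with '#'-prefixed metadata header lines."""
    from . import __version__
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# petkin {__version__}\n")
        for key, value in metadata.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False, float_format="%.6g")
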