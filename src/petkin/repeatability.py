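"""Test-retest repeatability: consistency ICC, VAR and AbsVAR.

The intraclass correlation uses the two-way random-effects consistency form
(single measures, k = 2 sessions): additive session effects are absorbed by
the column factor, so a constant offset between sessions leaves ICC = 1.
VAR and AbsVAR are the signed and absolute percent differences normalised by
the pair mean:

    VAR    = (1/N) sum 200 (retest_i - test_i) / (test_i + retest_i)
    AbsVAR = (1/N) sum 200 |test_i - retest_i| / (test_i + retest_i)
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RepeatMetrics",
    "icc_consistency",
    "icc_threshold",
    "var_metrics",
    "repeatability_table",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RepeatMetrics:
    """Repeatability summary for one region x parameter."""

    region: str
    parameter: str
    icc: float
    var_pct: float
    absvar_pct: float
    n_subjects: int


def _paired(test, retest) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(test, dtype=float)
    r = np.asarray(retest, dtype=float)
    if t.shape != r.shape or t.ndim != 1:
        raise ValueError("test and retest must be matching 1-D arrays")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
        raise ValueError("non-finite repeatability input")
    return t, r


def icc_consistency(test, retest) -> float:
    """Single-measure consistency ICC, ICC(C,1), for two sessions.

    From the two-way ANOVA decomposition with subjects as rows and sessions
    as columns: ``(MSR - MSE) / (MSR + (k-1) MSE)`` with k = 2. Negative
    values (within-subject variance exceeding between-subject variance) are
    reported as computed. Returns NaN when the data carry no variance at all.
    """
    t, r = _paired(test, retest)
    n = t.size
    if n < 2:
        raise ValueError("need at least 2 subjects")
    x = np.column_stack([t, r])
    k = 2
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse
    if denom == 0:
        warnings.warn("zero total variance: ICC undefined", stacklevel=2)
        return math.nan
    return float((msr - mse) / denom)


def icc_threshold(n_subjects: int, alpha: float = 0.05) -> float:
    """Smallest consistency ICC significantly greater than zero.

    Under the null the ANOVA ratio F = MSR/MSE follows F(n-1, n-1) for two
    sessions; inverting ICC = (F-1)/(F+1) at the upper alpha quantile gives
    the critical value (0.58 for n = 8 at alpha = 0.05). Decreases towards 0
    as n grows.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    fcrit = stats.f.ppf(1.0 - alpha, n_subjects - 1, n_subjects - 1)
    return float((fcrit - 1.0) / (fcrit + 1.0))


def var_metrics(test, retest) -> tuple[float, float]:
    """(VAR %, AbsVAR %) per the pair-mean-normalised difference formulas.

    Pairs summing to zero are undefined under this normalisation; they are
    excluded with a warning rather than propagating infinities.
    """
    t, r = _paired(test, retest)
    if t.size < 1:
        raise ValueError("need at least one pair")
    s = t + r
    ok = s != 0
    if not np.all(ok):
        warnings.warn(f"excluding {np.sum(~ok)} pair(s) with zero test+retest sum", stacklevel=2)
        t, r, s = t[ok], r[ok], s[ok]
        if t.size == 0:
            return math.nan, math.nan
    var = float(np.mean(200.0 * (r - t) / s))
    absvar = float(np.mean(200.0 * np.abs(t - r) / s))
    return var, absvar


def repeatability_table(
    estimates: pd.DataFrame,
    sessions: tuple[str, str] = ("S1", "S2"),
) -> pd.DataFrame:
    """Region x parameter repeatability table from long-format estimates.

    ``estimates`` needs columns ``subject, session, region, parameter,
    value``. Subjects missing either session are dropped (logged). Returns
    one row per region x parameter with ICC, VAR%, AbsVAR% and the session
    means - the shape of a test-retest summary table.
    """
    required = {"subject", "session", "region", "parameter", "value"}
    if not required.issubset(estimates.columns):
        raise ValueError(f"estimates must have columns {sorted(required)}")
    s1, s2 = sessions
    have = estimates.groupby("subject")["session"].agg(lambda s: set(s))
    complete = [subj for subj, seen in have.items() if {s1, s2} <= seen]
    dropped = sorted(set(have.index) - set(complete))
    if dropped:
        log.warning("dropping subjects without both sessions: %s", dropped)
    df = estimates[estimates["subject"].isin(complete)]

    rows = []
    for (region, parameter), grp in df.groupby(["region", "parameter"], sort=True):
        wide = grp.pivot_table(index="subject", columns="session", values="value")
        if s1 not in wide or s2 not in wide:
            continue
        wide = wide.dropna(subset=[s1, s2])
        t, r = wide[s1].to_numpy(), wide[s2].to_numpy()
        if t.size < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            icc = icc_consistency(t, r)
            var, absvar = var_metrics(t, r)
        rows.append({
            "region": region,
            "parameter": parameter,
            "n_subjects": int(t.size),
            "mean_S1": float(t.mean()),
            "mean_S2": float(r.mean()),
            "icc": icc,
            "var_pct": var,
            "absvar_pct": absvar,
        })
    return pd.DataFrame(rows)
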