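"""Paired condition comparisons: summaries, paired t-tests, pooled-SD
Cohen's d, and table assembly.

For each metric the Lo (Coasting/Following) and Hi (Braking/Steering)
conditions are summarized as mean +/- SD over retained windows; a paired
t-test runs on the trial-matched subset (inner join on trial id); and the
effect size is

    d = |m_lo - m_hi| / sqrt((s_lo^2 + s_hi^2) / 2),

the equal-weight pooled-SD convention, reported as an absolute value.  No
multiple-comparison correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateVarianceError
from .metrics import METRIC_ORDER, METRIC_UNITS

COMPARISON_COLUMNS = ["metric", "unit", "lo_mean", "lo_sd", "hi_mean",
                      "hi_sd", "t_stat", "df", "p_value", "cohens_d",
                      "n_pairs", "degenerate"]


@dataclass(frozen=True)
class PairedComparison:
    metric: str
    mean_lo: float
    sd_lo: float
    mean_hi: float
    sd_hi: float
    n_pairs: int
    t_stat: float
    df: int
    p_value: float
    cohens_d: float


def pair_windows(lo: pd.DataFrame, hi: pd.DataFrame
                 ) -> tuple[pd.DataFrame, int]:
    """Inner join of the two conditions on ``trial_id``.

    Returns the paired frame (``_lo``/``_hi`` column suffixes) and the number
    of trials dropped for missing either side.  Duplicate trial ids within a
    condition are a data error.
    """
    for name, df in (("lo", lo), ("hi", hi)):
        if df["trial_id"].duplicated().any():
            raise ValueError(f"duplicate trial_id in {name} condition")
    merged = lo.merge(hi, on="trial_id", suffixes=("_lo", "_hi"))
    n_dropped = len(lo) + len(hi) - 2 * len(merged)
    return merged, n_dropped


def paired_t(x, y) -> tuple[float, int, float]:
    """Paired t-test: t = mean(d) / (sd(d)/sqrt(n)) with d = x - y and the
    (n-1) sample SD; two-sided p from the t distribution with n-1 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateVarianceError("zero variance of paired differences")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


def cohens_d(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Absolute standardized mean difference with the equal-weight pooled SD
    sqrt((sd1^2 + sd2^2) / 2)."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0.0 and sd2 == 0.0:
        raise DegenerateVarianceError("effect size undefined: both SDs zero")
    return float(abs(mean1 - mean2) / np.sqrt((sd1 ** 2 + sd2 ** 2) / 2.0))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def comparison_table(lo: pd.DataFrame, hi: pd.DataFrame) -> pd.DataFrame:
    """One row per metric, in the canonical order (fixation count, fixation
    duration, horizontal/vertical mean gaze, horizontal/vertical spread of
    search, saccade amplitude).

    ``lo``/``hi`` are retained window-metric frames (exclusion already
    applied).  A metric absent in all windows of a condition, or with
    degenerate paired variance, yields a flagged row without statistics.
    """
    rows = []
    for metric in METRIC_ORDER:
        lo_vals = lo[metric].dropna()
        hi_vals = hi[metric].dropna()
        row = {"metric": metric, "unit": METRIC_UNITS[metric],
               "lo_mean": np.nan, "lo_sd": np.nan,
               "hi_mean": np.nan, "hi_sd": np.nan,
               "t_stat": np.nan, "df": np.nan, "p_value": np.nan,
               "cohens_d": np.nan, "n_pairs": 0, "degenerate": False}
        if len(lo_vals) == 0 or len(hi_vals) == 0:
            row["degenerate"] = True
            rows.append(row)
            continue
        row["lo_mean"] = float(lo_vals.mean())
        row["lo_sd"] = float(lo_vals.std(ddof=1))
        row["hi_mean"] = float(hi_vals.mean())
        row["hi_sd"] = float(hi_vals.std(ddof=1))
        paired, _ = pair_windows(lo[["trial_id", metric]].dropna(),
                                 hi[["trial_id", metric]].dropna())
        row["n_pairs"] = len(paired)
        try:
            t, df, p = paired_t(paired[f"{metric}_lo"], paired[f"{metric}_hi"])
            row.update(t_stat=t, df=df, p_value=p)
        except (ValueError, DegenerateVarianceError):
            row["degenerate"] = True
        try:
            row["cohens_d"] = round_half_up(cohens_d(
                row["lo_mean"], row["lo_sd"], row["hi_mean"], row["hi_sd"]))
        except DegenerateVarianceError:
            row["degenerate"] = True
        rows.append(row)
    return pd.DataFrame(rows, columns=COMPARISON_COLUMNS)
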