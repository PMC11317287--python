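"""Descriptive reconstitution summaries and the time-averaged abundance R.

R is the per-patient time average of a γδ subset count divided by the
TCRαβ count, taken over the post-transplant sampling days.  Because the
schedule (days +15, +30, +60, +100, +180, +240) is unevenly spaced, the
average is the trapezoidal integral of the ratio divided by the spanned
time — an arithmetic mean over visits would overweight the dense early
schedule.  Timepoints with αβ < 1 cell/µl are skipped: during early
aplasia the denominator makes the ratio meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, POST_DAYS

#: minimum αβ count (cells/µl) for a timepoint to enter the time average
AB_MIN = 1.0
#: pseudocount for log-ratios (cells/µl); never applied to R
LOG_RATIO_EPS = 0.5

#: relative (percentage) variables reported alongside absolute counts
RELATIVE_VARS: dict[str, tuple[str, str]] = {
    "cd4_pct_cd3": ("cd4", "cd3"),
    "cd8_pct_cd3": ("cd8", "cd3"),
    "ab_t_pct_cd3": ("ab_t", "cd3"),
    "gd_t_pct_cd3": ("gd_t", "cd3"),
    "vd1_pct_gd": ("vd1", "gd_t"),
    "vd2_pct_gd": ("vd2", "gd_t"),
    "non_pct_gd": ("non_vd1_vd2", "gd_t"),
}

STRATIFICATION_SUBSETS = ("gd_t", "vd1", "vd2")


@dataclass
class TimeAveragedAbundance:
    """Time-averaged subset/TCRαβ ratio for one patient."""

    patient_id: str
    subset: str
    R: float
    days_used: list[int]

    @property
    def eligible(self) -> bool:
        return len(self.days_used) >= 2


def summarize_timepoints(cohort: Cohort) -> pd.DataFrame:
    """Median/IQR per (variable x day) of absolute counts and percentages.

    Relative variables are computed per patient first, then summarized
    (median of ratios, not ratio of medians).  Quantiles use linear
    interpolation.  A day with zero observations is reported absent (NaN).
    """
    panels = cohort.panels[cohort.panels["day"] != "pre"]
    if panels.empty:
        raise ValueError("summarize_timepoints needs at least one post-HSCT panel row")
    from .cohort import COUNT_COLS
    rows = []
    days = sorted(panels["day"].astype(int).unique())
    for var in COUNT_COLS:
        for day in days:
            x = panels.loc[panels["day"].astype(int) == day, var].astype(float).dropna()
            rows.append(_qrow(var, day, x, "cells_per_ul"))
    for var, (num, den) in RELATIVE_VARS.items():
        for day in days:
            sub = panels[panels["day"].astype(int) == day]
            den_v = sub[den].astype(float)
            ratio = 100.0 * sub[num].astype(float) / den_v.where(den_v > 0)
            rows.append(_qrow(var, day, ratio.dropna(), "percent"))
    return pd.DataFrame(rows, columns=["variable", "day", "n", "median",
                                       "q1", "q3", "units"])


def _qrow(var: str, day: int, x: pd.Series, units: str) -> list:
    if len(x) == 0:
        return [var, day, 0, np.nan, np.nan, np.nan, units]
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return [var, day, len(x), med, q1, q3, units]


def time_average_abundance(panel: pd.DataFrame, subset: str) -> TimeAveragedAbundance:
    """Time-averaged subset/αβ ratio for one patient's panel rows.

    ``panel`` holds that patient's rows (any order); pre-transplant rows
    are ignored.  R = trapezoidal integral of subset(t)/αβ(t) over the
    usable days divided by the spanned time.  With fewer than two usable
    timepoints the patient is ineligible (R = NaN, days_used < 2).
    """
    pid = str(panel["patient_id"].iloc[0]) if len(panel) else ""
    post = panel[panel["day"] != "pre"].copy()
    post["day_num"] = post["day"].astype(int)
    post = post.sort_values("day_num")
    ab = post["ab_t"].astype(float).to_numpy()
    sub = post[subset].astype(float).to_numpy()
    t = post["day_num"].to_numpy(dtype=float)
    usable = np.isfinite(ab) & np.isfinite(sub) & (ab >= AB_MIN)
    t, ratio = t[usable], sub[usable] / ab[usable]
    if len(t) < 2:
        return TimeAveragedAbundance(pid, subset, float("nan"),
                                     [int(d) for d in t])
    r = float(np.trapezoid(ratio, t) / (t[-1] - t[0]))
    return TimeAveragedAbundance(pid, subset, r, [int(d) for d in t])


def abundance_table(cohort: Cohort,
                    subsets: tuple[str, ...] = STRATIFICATION_SUBSETS
                    ) -> pd.DataFrame:
    """Per-patient R for each subset; one row per (patient, subset)."""
    rows = []
    for pid, panel in cohort.panels.groupby("patient_id", sort=True):
        for subset in subsets:
            taa = time_average_abundance(panel, subset)
            rows.append([pid, subset, taa.R, len(taa.days_used),
                         ";".join(str(d) for d in taa.days_used)])
    return pd.DataFrame(rows, columns=["patient_id", "subset", "R",
                                       "n_days_used", "days_used"])


def vdelta_log_ratio(vd2, vd1) -> float | np.ndarray:
    """ln((vd2+ε)/(vd1+ε)) with pseudocount ε = 0.5 cells/µl.

    Symmetric in the pseudocount: equal counts (including 0/0) give 0.
    """
    eps = LOG_RATIO_EPS
    vd2 = np.asarray(vd2, dtype=float)
    vd1 = np.asarray(vd1, dtype=float)
    out = np.log((vd2 + eps) / (vd1 + eps))
    return float(out) if out.ndim == 0 else out


def vdelta_ratio_trajectory(cohort: Cohort, groups: pd.Series | None = None
                            ) -> pd.DataFrame:
    """Group-median log Vδ2/Vδ1 ratio per post-HSCT day.

    ``groups`` maps patient_id -> group label; None summarizes the whole
    cohort as one group.
    """
    panels = cohort.panels[cohort.panels["day"] != "pre"].copy()
    panels["day_num"] = panels["day"].astype(int)
    panels["log_ratio"] = vdelta_log_ratio(panels["vd2"].astype(float),
                                           panels["vd1"].astype(float))
    if groups is None:
        groups = pd.Series("all", index=panels["patient_id"].unique())
    panels["group"] = panels["patient_id"].map(groups)
    med = (panels.dropna(subset=["group"])
           .groupby(["group", "day_num"])["log_ratio"]
           .median().reset_index())
    return med.rename(columns={"day_num": "day", "log_ratio": "median_log_ratio"})
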