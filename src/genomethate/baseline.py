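"""Observed baseline quantities derived from pre/post-treatment triglycerides.

Everything downstream of the raw phenotype table is computed on the natural-log
scale: per subject j,

    O_preRx_TG_j  = mean(ln TG1_j, ln TG2_j)
    O_postRx_TG_j = mean(ln TG3_j, ln TG4_j)
    O_delta_TG_j  = O_postRx_TG_j - O_preRx_TG_j
    O_daysRx_j    = mean(draw_date_v3_j, draw_date_v4_j) - draw_date_v2_j
    O_slope_TG_j  = O_delta_TG_j / O_daysRx_j
    O_preZ_j      = (O_preRx_TG_j - mean) / sd   over the cohort

Sample moments use the n-1 denominator throughout, so standardization and the
later rescaling of simulated slopes cancel exactly.  Subjects missing
post-treatment TG or draw dates get missing O_postRx/O_slope (never imputed);
cohort slope moments are over complete cases.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ObservedBaseline",
    "derive_pre_post",
    "compute_daysRx",
    "compute_slope",
    "standardize_baseline",
    "derive_baseline",
]

TG_COLUMNS = ["TG1", "TG2", "TG3", "TG4"]
DATE_COLUMNS = ["DRAWDATE_V2", "DRAWDATE_V3", "DRAWDATE_V4"]


@dataclass
class ObservedBaseline:
    """Per-subject derived quantities plus the cohort moments used downstream.

    ``table`` is indexed by subject_id with columns O_preRx_TG, O_postRx_TG,
    O_delta_TG, O_daysRx, O_slope_TG, O_preZ.
    """

    table: pd.DataFrame
    mean_preRx: float
    sd_preRx: float
    mean_slope: float
    sd_slope: float

    @property
    def complete(self) -> pd.Series:
        """Boolean mask of subjects with a defined observed slope."""
        return self.table["O_slope_TG"].notna()


def _log_pair_mean(a, b, label: str) -> pd.Series:
    a = pd.to_numeric(pd.Series(a), errors="coerce")
    b = pd.to_numeric(pd.Series(b), errors="coerce")
    bad = ((a <= 0) | (b <= 0)).fillna(False)
    if bad.any():
        raise ValueError(f"non-positive TG values for {label} (first at row {bad.idxmax()})")
    return (np.log(a) + np.log(b)) / 2.0


def derive_pre_post(pheno: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Mean log-TG before (visits 1-2) and after (visits 3-4) treatment.

    Missing TG3/TG4 yields a missing post value for that subject, not zero.
    """
    pre = _log_pair_mean(pheno["TG1"], pheno["TG2"], "preRx")
    post = _log_pair_mean(pheno["TG3"], pheno["TG4"], "postRx")
    return pre, post


def _as_day_numbers(col: pd.Series) -> pd.Series:
    """Accept integer/float day numbers or ISO calendar dates."""
    num = pd.to_numeric(col, errors="coerce")
    if num.notna().sum() == col.notna().sum():
        return num.astype(float)
    dates = pd.to_datetime(col, errors="coerce", format="mixed")
    return (dates - pd.Timestamp("1970-01-01")) / pd.Timedelta(days=1)


def compute_daysRx(pheno: pd.DataFrame) -> pd.Series:
    """Days on treatment: mean(v3, v4 draw dates) minus the v2 draw date."""
    v2 = _as_day_numbers(pheno["DRAWDATE_V2"])
    v3 = _as_day_numbers(pheno["DRAWDATE_V3"])
    v4 = _as_day_numbers(pheno["DRAWDATE_V4"])
    days = (v3 + v4) / 2.0 - v2
    nonpos = (days <= 0).fillna(False)
    if nonpos.any():
        raise ValueError(
            f"non-positive treatment duration (first at row {nonpos.idxmax()}); "
            "slope is undefined"
        )
    return days


def compute_slope(delta: pd.Series, daysRx: pd.Series) -> pd.Series:
    """Change in log-TG per day of treatment."""
    if (pd.Series(daysRx) == 0).any():
        raise ValueError("zero treatment duration; slope is undefined")
    return delta / daysRx


def standardize_baseline(preRx: pd.Series) -> tuple[pd.Series, float, float]:
    """Z-score the baseline log-TG over the cohort (n-1 SD convention).

    Returns (z, mean, sd).  Subjects with missing baseline stay missing and do
    not enter the moments.
    """
    vals = preRx.dropna()
    if len(vals) < 2:
        raise ValueError("need at least 2 baseline values to standardize")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd == 0:
        raise ValueError("baseline log-TG has zero variance; cannot standardize")
    return (preRx - mean) / sd, mean, sd


def derive_baseline(pheno: pd.DataFrame) -> ObservedBaseline:
    """Derive every observed baseline quantity from a phenotype table.

    ``pheno`` needs columns subject_id, TG1..TG4, DRAWDATE_V2..V4.  TG3/TG4 and
    the draw dates may be missing for some subjects.
    """
    pheno = pheno.reset_index(drop=True)
    pre = _log_pair_mean(pheno["TG1"], pheno["TG2"], "preRx")

    tg3 = pd.to_numeric(pheno["TG3"], errors="coerce")
    tg4 = pd.to_numeric(pheno["TG4"], errors="coerce")
    if ((tg3 <= 0) | (tg4 <= 0)).fillna(False).any():
        raise ValueError("non-positive TG values for postRx")
    post = (np.log(tg3) + np.log(tg4)) / 2.0

    have_dates = pheno[DATE_COLUMNS].notna().all(axis=1)
    days = pd.Series(np.nan, index=pheno.index)
    if have_dates.any():
        days[have_dates] = compute_daysRx(pheno.loc[have_dates]).values

    delta = post - pre
    slope = delta / days

    preZ, mean_pre, sd_pre = standardize_baseline(pre)
    complete = slope.notna()
    if complete.sum() < 2:
        raise ValueError("need at least 2 subjects with complete data for slope moments")
    mean_slope = float(slope[complete].mean())
    sd_slope = float(slope[complete].std(ddof=1))

    table = pd.DataFrame(
        {
            "O_preRx_TG": pre,
            "O_postRx_TG": post,
            "O_delta_TG": delta,
            "O_daysRx": days,
            "O_slope_TG": slope,
            "O_preZ": preZ,
        }
    )
    table.index = pd.Index(pheno["subject_id"], name="subject_id")
    return ObservedBaseline(
        table=table,
        mean_preRx=mean_pre,
        sd_preRx=sd_pre,
        mean_slope=mean_slope,
        sd_slope=sd_slope,
    )
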