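"""Deterministic derived-variable computation for renal-function analyses.

Estimated glomerular filtration rate (eGFR) from serum creatinine via the
2009 creatinine-based CKD-EPI equation, annualised percentage changes in
eGFR and weight, urine albumin/creatinine categorisation, and aggregation
of irregular eGFR series into annual averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25

#: eGFR floor (ml/min/1.73m^2) used wherever a variance proportional to the
#: mean must stay positive.
EGFR_FLOOR = 5.0

__all__ = [
    "DAYS_PER_YEAR",
    "EGFR_FLOOR",
    "EgfrPoint",
    "ckd_epi_egfr",
    "inverse_ckd_epi_creatinine",
    "annual_pct_egfr_change",
    "annual_pct_weight_change",
    "albuminuria_category",
    "annualize_egfr",
]


@dataclass(frozen=True)
class EgfrPoint:
    """One eGFR observation: value plus time in years since the patient's
    initial (first qualifying) eGFR."""

    patient_id: str
    time: float
    date: date
    egfr: float

    def __post_init__(self) -> None:
        if not self.egfr > 0:
            raise ValueError(f"eGFR must be positive, got {self.egfr}")
        if self.time < 0:
            raise ValueError(f"time must be >= 0, got {self.time}")


def ckd_epi_egfr(scr, age, is_female, is_black):
    """eGFR (ml/min/1.73m^2) from the 2009 creatinine CKD-EPI equation.

    eGFR = 141 * min(Scr/kappa, 1)^alpha * max(Scr/kappa, 1)^-1.209
           * 0.993^age * 1.018 [if female] * 1.159 [if black]

    with kappa = 0.7 (female) / 0.9 (male) and alpha = -0.329 (female) /
    -0.411 (male).  Vectorised over all arguments.

    Parameters
    ----------
    scr : float or array
        Serum creatinine, mg/dL. Must be positive.
    age : float or array
        Age in years. Must be positive.
    is_female, is_black : bool or array
        Sex and race indicators of the 4-variable equation.
    """
    scr = np.asarray(scr, dtype=float)
    age = np.asarray(age, dtype=float)
    is_female = np.asarray(is_female, dtype=bool)
    is_black = np.asarray(is_black, dtype=bool)
    if np.any(scr <= 0):
        raise ValueError("serum creatinine must be positive")
    if np.any(age <= 0):
        raise ValueError("age must be positive")

    kappa = np.where(is_female, 0.7, 0.9)
    alpha = np.where(is_female, -0.329, -0.411)
    ratio = scr / kappa
    egfr = (
        141.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.209
        * 0.993**age
        * np.where(is_female, 1.018, 1.0)
        * np.where(is_black, 1.159, 1.0)
    )
    if egfr.ndim == 0:
        return float(egfr)
    return egfr


def inverse_ckd_epi_creatinine(egfr, age, is_female, is_black):
    """Serum creatinine (mg/dL) whose CKD-EPI eGFR equals ``egfr``.

    The equation is strictly decreasing in creatinine, so the inverse is
    unique: on the low-creatinine branch (Scr < kappa) the exponent is
    alpha, on the high branch it is -1.209.
    """
    egfr = np.asarray(egfr, dtype=float)
    age = np.asarray(age, dtype=float)
    is_female = np.asarray(is_female, dtype=bool)
    is_black = np.asarray(is_black, dtype=bool)
    if np.any(egfr <= 0):
        raise ValueError("eGFR must be positive")

    kappa = np.where(is_female, 0.7, 0.9)
    alpha = np.where(is_female, -0.329, -0.411)
    base = (
        141.0
        * 0.993**age
        * np.where(is_female, 1.018, 1.0)
        * np.where(is_black, 1.159, 1.0)
    )
    g = egfr / base  # = min(r,1)^alpha * max(r,1)^-1.209 at r = scr/kappa
    # g > 1 <=> r < 1 (low branch, exponent alpha); g < 1 <=> high branch.
    scr = kappa * np.where(g >= 1.0, g ** (1.0 / alpha), g ** (1.0 / -1.209))
    if scr.ndim == 0:
        return float(scr)
    return scr


def annual_pct_egfr_change(initial_egfr, t0_egfr, initial_date, t0_date):
    """Annualised percentage eGFR change between the initial and T0 values:

    [(T0 eGFR - initial eGFR) / initial eGFR] / [(T0 date - initial date)
    / 365.25] * 100, in %/year.
    """
    if initial_egfr <= 0:
        raise ValueError("initial eGFR must be positive")
    dt_days = (pd.Timestamp(t0_date) - pd.Timestamp(initial_date)).days
    if dt_days <= 0:
        raise ValueError("T0 date must be after the initial date")
    years = dt_days / DAYS_PER_YEAR
    return (t0_egfr - initial_egfr) / initial_egfr / years * 100.0


def annual_pct_weight_change(weights: pd.DataFrame) -> float:
    """Annualised % change between a patient's first and last pre-T0 weight.

    ``weights`` has columns ``date`` and ``value`` (lb). Returns NaN (the
    missing-value sentinel, not an exception) when fewer than two distinct
    dates are available: patients without weight stay in the cohort and only
    drop out of the weight-adjusted models.
    """
    if weights is None or len(weights) < 2:
        return float("nan")
    w = weights.sort_values("date")
    first, last = w.iloc[0], w.iloc[-1]
    dt_days = (pd.Timestamp(last["date"]) - pd.Timestamp(first["date"])).days
    if dt_days <= 0:
        return float("nan")
    years = dt_days / DAYS_PER_YEAR
    return 100.0 * (last["value"] - first["value"]) / first["value"] / years


def albuminuria_category(uacr: float) -> str:
    """Categorise a urine micro-albumin/creatinine ratio (mg/g).

    <20 normal; 20-300 (closed interval) microalbuminuria; >300 albuminuria.
    """
    if uacr < 0:
        raise ValueError("UACR must be non-negative")
    if uacr < 20.0:
        return "normal"
    if uacr <= 300.0:
        return "microalbuminuria"
    return "albuminuria"


def annualize_egfr(points: pd.DataFrame, t0_date, max_years: int = 9) -> pd.DataFrame:
    """Collapse post-T0 eGFR measurements into annual averages.

    Years after T0 are half-open intervals [T0 + k yr, T0 + (k+1) yr) with
    a 365.25-day year, k = 0..max_years-1; a measurement exactly on a year
    boundary therefore belongs to the later year.  Years with no
    measurements are absent from the output (missing, not zero).

    Parameters
    ----------
    points : DataFrame with columns patient_id, date, egfr.
    t0_date : scalar date, or a mapping/Series patient_id -> T0 date.

    Returns
    -------
    DataFrame with columns patient_id, year_index, mean_egfr, n_measurements.
    """
    cols = ["patient_id", "year_index", "mean_egfr", "n_measurements"]
    if points is None or len(points) == 0:
        return pd.DataFrame(columns=cols)
    df = points[["patient_id", "date", "egfr"]].copy()
    df["date"] = pd.to_datetime(df["date"])
    if isinstance(t0_date, (pd.Series, dict)):
        t0 = df["patient_id"].map(t0_date)
        t0 = pd.to_datetime(t0)
    else:
        t0 = pd.Series(pd.Timestamp(t0_date), index=df.index)
    days = (df["date"] - t0).dt.days
    df["year_index"] = np.floor(days / DAYS_PER_YEAR).astype(int)
    df = df[(df["year_index"] >= 0) & (df["year_index"] < max_years)]
    if len(df) == 0:
        return pd.DataFrame(columns=cols)
    out = (
        df.groupby(["patient_id", "year_index"], sort=True)["egfr"]
        .agg(mean_egfr="mean", n_measurements="count")
        .reset_index()
    )
    out["n_measurements"] = out["n_measurements"].astype(int)
    return out[cols]
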