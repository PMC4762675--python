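"""Cohort assembly: inclusion/exclusion rules, T0 definition, baseline capture.

Builds the analysis table for an early-CKD-stage-3 cohort: patients enter if
their first eGFR inside the slope-assessment window lies in [45, 60]
ml/min/1.73m^2 and (under the primary configuration) a second in-range eGFR
exists at least 90 days later.  T0 — the start of survival follow-up — is
the date of the last eGFR measurement on or before the end of the slope
window.  Baseline covariates are captured from the 5 years preceding T0.
Sensitivity-analysis variants (wider slope window, washout exclusions,
minimum measurement counts, ESRD handling) are configuration, not code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .egfr_core import (
    DAYS_PER_YEAR,
    albuminuria_category,
    annual_pct_egfr_change,
    annual_pct_weight_change,
    ckd_epi_egfr,
)
from .synthetic import COMORBIDITIES

__all__ = [
    "CohortConfig",
    "build_cohort",
    "capture_baseline",
    "egfr_series",
    "pre_t0_points",
    "post_t0_points",
]


@dataclass(frozen=True)
class CohortConfig:
    slope_window: tuple = ("1999-10-01", "2004-09-30")
    trajectory_window: tuple = ("2004-10-01", "2013-09-30")
    egfr_range: tuple = (45.0, 60.0)  # inclusive bounds
    require_second_qualifying_egfr: bool = True
    #: stricter reading: the second qualifying eGFR must also fall in the
    #: final (enrollment) year of the slope window
    second_egfr_in_enrollment_year: bool = False
    min_gap_days: int = 90
    washout_exclusion: bool = False
    washout_flag_columns: tuple = ("aki", "hospitalization")
    washout_years: float = 2.0
    min_egfr_measurements_pre_t0: int = 0
    esrd_handling: str = "keep"  # exclude | censor | keep
    esrd_egfr_threshold: float = 15.0
    baseline_years: float = 5.0

    def __post_init__(self) -> None:
        lo = pd.Timestamp(self.slope_window[0])
        hi = pd.Timestamp(self.slope_window[1])
        t_lo = pd.Timestamp(self.trajectory_window[0])
        t_hi = pd.Timestamp(self.trajectory_window[1])
        if not (lo < hi <= t_lo < t_hi):
            raise ValueError("windows must be ordered and non-overlapping")
        if self.esrd_handling not in ("exclude", "censor", "keep"):
            raise ValueError("esrd_handling must be exclude, censor or keep")


def egfr_series(measurements: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    """Per-patient eGFR observations (patient_id, date, egfr), with same-day
    values averaged.  Rows with analyte ``egfr`` are used directly; rows with
    ``creatinine_mg_dl`` are converted via CKD-EPI using the patient's age at
    the measurement date, sex and race.  Raises on duplicate
    (patient, date, analyte) rows, naming the offending patient."""
    m = measurements.copy()
    m["date"] = pd.to_datetime(m["date"])
    dup = m.duplicated(["patient_id", "date", "analyte"], keep=False)
    if dup.any():
        pid = m.loc[dup, "patient_id"].iloc[0]
        raise ValueError(
            f"duplicate (patient, date, analyte) measurement rows for patient {pid}"
        )
    frames = []
    direct = m[m["analyte"] == "egfr"]
    if len(direct):
        frames.append(direct[["patient_id", "date", "value"]].rename(
            columns={"value": "egfr"}
        ))
    scr = m[m["analyte"] == "creatinine_mg_dl"]
    if len(scr):
        meta = patients.set_index("patient_id")
        scr = scr.merge(
            meta[["birth_date", "sex", "race"]],
            left_on="patient_id",
            right_index=True,
            how="left",
        )
        age = (scr["date"] - pd.to_datetime(scr["birth_date"])).dt.days / DAYS_PER_YEAR
        egfr = ckd_epi_egfr(
            scr["value"].to_numpy(),
            age.to_numpy(),
            (scr["sex"] == "F").to_numpy(),
            (scr["race"] == "black").to_numpy(),
        )
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": scr["patient_id"].to_numpy(),
                    "date": scr["date"].to_numpy(),
                    "egfr": egfr,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["patient_id", "date", "egfr"])
    out = pd.concat(frames, ignore_index=True)
    out = (
        out.groupby(["patient_id", "date"], as_index=False)["egfr"]
        .mean()
        .sort_values(["patient_id", "date"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def capture_baseline(
    patient_id,
    t0_date,
    measurements: pd.DataFrame,
    patients: pd.DataFrame,
    flag_events: pd.DataFrame | None = None,
    baseline_years: float = 5.0,
) -> dict:
    """Baseline covariate block for one patient, using only data dated within
    [T0 - baseline_years, T0].

    Comorbidity flags come from the static 0/1 columns of ``patients``
    unless a dated ``flag_events`` table (patient_id, condition, date) is
    supplied, in which case a flag is 1 only if an event falls inside the
    baseline window.  Weight change and albuminuria use window-restricted
    measurements; absent data yield missing sentinels (NaN / None).
    """
    t0 = pd.Timestamp(t0_date)
    start = t0 - pd.Timedelta(days=round(baseline_years * DAYS_PER_YEAR))
    m = measurements[measurements["patient_id"] == patient_id].copy()
    m["date"] = pd.to_datetime(m["date"])
    win = m[(m["date"] >= start) & (m["date"] <= t0)]

    out: dict = {}
    if flag_events is not None:
        ev = flag_events[flag_events["patient_id"] == patient_id].copy()
        ev["date"] = pd.to_datetime(ev["date"])
        ev = ev[(ev["date"] >= start) & (ev["date"] <= t0)]
        present = set(ev["condition"])
        for c in COMORBIDITIES:
            out[c] = int(c in present)
    else:
        row = patients.loc[patients["patient_id"] == patient_id].iloc[0]
        for c in COMORBIDITIES:
            out[c] = int(row[c]) if c in patients.columns else 0

    weights = win[win["analyte"] == "weight_lb"][["date", "value"]]
    out["annual_pct_weight_change"] = annual_pct_weight_change(weights)

    uacr = win[win["analyte"] == "uacr_mg_g"].sort_values("date")
    out["albuminuria_category"] = (
        albuminuria_category(float(uacr["value"].iloc[-1])) if len(uacr) else None
    )
    return out


def build_cohort(
    measurements: pd.DataFrame,
    patients: pd.DataFrame,
    config: CohortConfig = CohortConfig(),
    flag_events: pd.DataFrame | None = None,
):
    """Apply the inclusion/exclusion rules and assemble the analysis table.

    Returns (cohort, exclusions): one CohortRow per included patient, and a
    log recording, per excluded patient, the first rule that removed them.
    Exclusion counts plus the cohort size always sum to the input count.
    """
    win_lo = pd.Timestamp(config.slope_window[0])
    win_hi = pd.Timestamp(config.slope_window[1])
    study_end = pd.Timestamp(config.trajectory_window[1])
    enroll_lo = win_hi - pd.Timedelta(days=round(DAYS_PER_YEAR))

    pats = patients.copy()
    pats["birth_date"] = pd.to_datetime(pats["birth_date"], errors="coerce")
    pats["death_date"] = pd.to_datetime(
        pats.get("death_date"), errors="coerce"
    )
    all_ids = pats["patient_id"].tolist()
    excluded: dict[str, tuple[str, int]] = {}
    rule_order = 0

    def exclude(ids, reason):
        nonlocal rule_order
        rule_order += 1
        for pid in ids:
            if pid not in excluded:
                excluded[pid] = (reason, rule_order)

    # rule 1: unusable demographics
    exclude(pats.loc[pats["birth_date"].isna(), "patient_id"], "missing birth date")

    # rule 2: dialysis or kidney transplant before T0 (input flag columns)
    for col in ("dialysis", "transplant"):
        if col in pats.columns:
            exclude(
                pats.loc[pats[col].astype(float) == 1, "patient_id"],
                "dialysis or transplant",
            )

    egfr = egfr_series(measurements, pats)
    in_win = egfr[(egfr["date"] >= win_lo) & (egfr["date"] <= win_hi)]

    # rule 3: no eGFR inside the slope-assessment window
    have = set(in_win["patient_id"])
    exclude([p for p in all_ids if p not in have], "no eGFR in slope window")

    # rule 4: initial (first in-window) eGFR outside [45, 60]
    first = in_win.groupby("patient_id", as_index=False).first()
    first = first.rename(columns={"date": "initial_date", "egfr": "initial_egfr"})
    lo, hi = config.egfr_range
    bad = first[(first["initial_egfr"] < lo) | (first["initial_egfr"] > hi)]
    exclude(bad["patient_id"], "initial eGFR out of range")

    # rule 5: second qualifying in-range eGFR >= 90 days after the initial
    if config.require_second_qualifying_egfr:
        cand = in_win.merge(
            first[["patient_id", "initial_date"]], on="patient_id"
        )
        gap = (cand["date"] - cand["initial_date"]).dt.days
        ok = (
            (gap >= config.min_gap_days)
            & (cand["egfr"] >= lo)
            & (cand["egfr"] <= hi)
        )
        if config.second_egfr_in_enrollment_year:
            ok &= cand["date"] > enroll_lo
        qualified = set(cand.loc[ok, "patient_id"])
        exclude(
            [p for p in first["patient_id"] if p not in qualified],
            "no second qualifying eGFR",
        )

    # T0: last eGFR on or before the end of the slope window
    t0 = (
        in_win.groupby("patient_id", as_index=False)
        .last()
        .rename(columns={"date": "t0_date", "egfr": "t0_egfr"})
    )
    table = first.merge(t0, on="patient_id")

    # rule 6: washout exclusions (sensitivity analyses)
    if config.washout_exclusion:
        for col in config.washout_flag_columns:
            if col in pats.columns:
                exclude(
                    pats.loc[pats[col].astype(float) == 1, "patient_id"],
                    "AKI or hospitalization during washout",
                )

    # rule 7: minimum number of pre-T0 eGFR measurement dates
    pre_counts = (
        in_win.merge(t0[["patient_id", "t0_date"]], on="patient_id")
        .query("date <= t0_date")
        .groupby("patient_id")
        .size()
    )
    table["n_egfr_pre_t0"] = (
        table["patient_id"].map(pre_counts).fillna(0).astype(int)
    )
    if config.min_egfr_measurements_pre_t0 > 0:
        short = table[
            table["n_egfr_pre_t0"] < config.min_egfr_measurements_pre_t0
        ]
        exclude(
            short["patient_id"],
            f"fewer than {config.min_egfr_measurements_pre_t0} eGFR measurements",
        )

    # rule 8: ESRD (any outpatient eGFR below threshold)
    esrd_first = (
        egfr[egfr["egfr"] < config.esrd_egfr_threshold]
        .groupby("patient_id")["date"]
        .min()
    )
    if config.esrd_handling == "exclude":
        exclude(esrd_first.index, "ESRD (eGFR < 15)")

    # survival outcome
    table = table.merge(
        pats[["patient_id", "birth_date", "sex", "race", "death_date"]],
        on="patient_id",
    )
    for c in COMORBIDITIES:
        table[c] = (
            table["patient_id"]
            .map(pats.set_index("patient_id")[c])
            .astype(int)
            if c in pats.columns
            else 0
        )

    # rule 9: death on or before T0 (no follow-up time)
    dead_early = table[
        table["death_date"].notna() & (table["death_date"] <= table["t0_date"])
    ]
    exclude(dead_early["patient_id"], "death on or before T0")

    table = table[~table["patient_id"].isin(excluded)].reset_index(drop=True)

    end = table["death_date"].fillna(study_end).clip(upper=study_end)
    if config.esrd_handling == "censor":
        esrd_date = table["patient_id"].map(esrd_first)
        end = pd.concat([end, esrd_date], axis=1).min(axis=1)
        end = end.clip(lower=table["t0_date"] + pd.Timedelta(days=1))
    table["death_flag"] = (
        table["death_date"].notna() & (table["death_date"] <= end)
    ).astype(int)
    table["followup_time"] = (
        (end - table["t0_date"]).dt.days / DAYS_PER_YEAR
    )

    table["age_at_t0"] = (
        (table["t0_date"] - table["birth_date"]).dt.days / DAYS_PER_YEAR
    )
    table["annual_pct_egfr_change"] = [
        annual_pct_egfr_change(r.initial_egfr, r.t0_egfr, r.initial_date, r.t0_date)
        if r.t0_date > r.initial_date
        else float("nan")
        for r in table.itertuples()
    ]

    # baseline weight change and albuminuria, window-restricted (vectorised)
    m = measurements.copy()
    m["date"] = pd.to_datetime(m["date"])
    t0_map = table.set_index("patient_id")["t0_date"]
    base_days = round(config.baseline_years * DAYS_PER_YEAR)
    m = m[m["patient_id"].isin(t0_map.index)]
    m_t0 = m["patient_id"].map(t0_map)
    in_base = (m["date"] <= m_t0) & (
        m["date"] >= m_t0 - pd.Timedelta(days=base_days)
    )
    mb = m[in_base]

    w = mb[mb["analyte"] == "weight_lb"].sort_values("date")
    wg = w.groupby("patient_id")
    w_first = wg[["date", "value"]].first()
    w_last = wg[["date", "value"]].last()
    dt_years = (w_last["date"] - w_first["date"]).dt.days / DAYS_PER_YEAR
    w_change = (
        100.0 * (w_last["value"] - w_first["value"]) / w_first["value"] / dt_years
    ).where(dt_years > 0)
    table["annual_pct_weight_change"] = table["patient_id"].map(w_change)

    ua = mb[mb["analyte"] == "uacr_mg_g"].sort_values("date")
    ua_last = ua.groupby("patient_id")["value"].last()
    table["albuminuria_category"] = table["patient_id"].map(
        ua_last.map(albuminuria_category)
    )

    if flag_events is not None:
        ev = flag_events.copy()
        ev["date"] = pd.to_datetime(ev["date"])
        ev_t0 = ev["patient_id"].map(t0_map)
        ev = ev[
            (ev["date"] <= ev_t0)
            & (ev["date"] >= ev_t0 - pd.Timedelta(days=base_days))
        ]
        flagged = ev.groupby(["patient_id", "condition"]).size().unstack(
            fill_value=0
        )
        for c in COMORBIDITIES:
            table[c] = (
                table["patient_id"]
                .map(flagged[c] if c in flagged.columns else pd.Series(dtype=int))
                .fillna(0)
                .astype(int)
                .clip(upper=1)
            )

    cols = [
        "patient_id",
        "t0_date",
        "initial_date",
        "initial_egfr",
        "t0_egfr",
        "age_at_t0",
        "sex",
        "race",
        *COMORBIDITIES,
        "annual_pct_egfr_change",
        "annual_pct_weight_change",
        "albuminuria_category",
        "n_egfr_pre_t0",
        "followup_time",
        "death_flag",
    ]
    cohort = table[cols].reset_index(drop=True)

    exclusions = pd.DataFrame(
        [
            {"patient_id": pid, "reason": reason, "rule_order": order}
            for pid, (reason, order) in sorted(excluded.items())
        ],
        columns=["patient_id", "reason", "rule_order"],
    )
    assert len(cohort) + len(exclusions) == len(all_ids)
    return cohort, exclusions


def pre_t0_points(
    measurements: pd.DataFrame,
    patients: pd.DataFrame,
    cohort: pd.DataFrame,
    config: CohortConfig = CohortConfig(),
) -> pd.DataFrame:
    """eGFR observations feeding the slope model: each included patient's
    eGFR values from their initial measurement through T0, with ``time`` in
    years since the patient's own initial eGFR."""
    egfr = egfr_series(measurements, patients)
    egfr = egfr.merge(
        cohort[["patient_id", "initial_date", "t0_date"]], on="patient_id"
    )
    egfr = egfr[
        (egfr["date"] >= egfr["initial_date"]) & (egfr["date"] <= egfr["t0_date"])
    ].copy()
    egfr["time"] = (egfr["date"] - egfr["initial_date"]).dt.days / DAYS_PER_YEAR
    return egfr[["patient_id", "date", "time", "egfr"]].reset_index(drop=True)


def post_t0_points(
    measurements: pd.DataFrame,
    patients: pd.DataFrame,
    cohort: pd.DataFrame,
    config: CohortConfig = CohortConfig(),
) -> pd.DataFrame:
    """eGFR observations inside the trajectory window, after each patient's
    T0 and within their follow-up."""
    lo = pd.Timestamp(config.trajectory_window[0])
    hi = pd.Timestamp(config.trajectory_window[1])
    egfr = egfr_series(measurements, patients)
    egfr = egfr.merge(cohort[["patient_id", "t0_date"]], on="patient_id")
    egfr = egfr[
        (egfr["date"] > egfr["t0_date"])
        & (egfr["date"] >= lo)
        & (egfr["date"] <= hi)
    ].copy()
    return egfr[["patient_id", "date", "egfr"]].reset_index(drop=True)
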