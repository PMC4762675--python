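"""Seeded synthetic longitudinal cohorts for renal-function trajectory analysis.

Emulates the statistical structure the downstream stages assume: irregularly
timed eGFR series with per-patient random intercepts and slopes drawn by
latent slope class (improved / stable / declining), residual variance
proportional to the mean eGFR, covariate-linked class membership, latent
post-cutover trajectory groups, informative dropout tied to death, and
covariate-linked survival.  All randomness flows from a single seed; an
identical (config, seed) pair reproduces a byte-identical export.

Calendar anchoring follows the study design the analysis stages expect:
the slope-assessment window runs 1999-10-01 .. 2004-09-30 and follow-up
for trajectories and death runs to 2013-09-30.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .egfr_core import DAYS_PER_YEAR, EGFR_FLOOR, inverse_ckd_epi_creatinine

PRE_WINDOW_START = pd.Timestamp("1999-10-01")
FIRST_VISIT_END = pd.Timestamp("2003-09-30")
CUTOVER_DATE = pd.Timestamp("2004-09-30")
STUDY_END = pd.Timestamp("2013-09-30")

CLASS_NAMES = ("improved", "stable", "declining")

COMORBIDITIES = (
    "diabetes",
    "hypertension",
    "cardiovascular_disease",
    "hyperlipidemia",
    "peripheral_artery_disease",
    "cerebrovascular_disease",
    "chronic_lung_disease",
    "hepatitis_c",
    "hiv",
    "dementia",
)

#: Baseline comorbidity prevalences, roughly those of an elderly male
#: veteran cohort with early CKD stage 3.
DEFAULT_PREVALENCES = {
    "diabetes": 0.37,
    "hypertension": 0.85,
    "cardiovascular_disease": 0.49,
    "hyperlipidemia": 0.73,
    "peripheral_artery_disease": 0.054,
    "cerebrovascular_disease": 0.010,
    "chronic_lung_disease": 0.244,
    "hepatitis_c": 0.015,
    "hiv": 0.061,
    "dementia": 0.046,
}

#: Multinomial-logit class effects (log-odds vs stable) of selected
#: comorbidities on slope-class membership: covariate -> (improved, declining).
DEFAULT_CLASS_LOGITS = {
    "diabetes": (0.14, 0.67),
    "hypertension": (0.10, 0.63),
    "chronic_lung_disease": (0.28, 0.27),
}


@dataclass(frozen=True)
class TrajectoryGroupTruth:
    """One latent post-cutover trajectory group for the improved class."""

    share: float
    intercept: float  # mean eGFR at the cutover date, ml/min/1.73m^2
    slope: float  # ml/min/1.73m^2 per year after cutover
    log_hr: float  # additive log-hazard of death for members


#: Default latent groups: a high-intercept rising group, an intermediate
#: mildly declining group, and a low-intercept fast-declining group, with
#: the highest mortality hazard planted on the high-intercept rising group.
DEFAULT_TRAJECTORY_GROUPS = (
    TrajectoryGroupTruth(0.15, 80.0, 0.5, 0.60),
    TrajectoryGroupTruth(0.60, 62.0, -1.5, 0.10),
    TrajectoryGroupTruth(0.25, 50.0, -3.5, 0.35),
)


@dataclass(frozen=True)
class DropoutLink:
    """Couples the hazard of death and measurement cessation to the latent
    structure.  Death times are exponential from the cutover date with a
    log-linear hazard; cessation makes a dying patient's series stop up to
    two years before death, with a class-specific probability — this is the
    informative-missingness mechanism."""

    baseline_hazard: float = 0.053  # events / person-year from cutover
    class_log_hr: tuple = (0.0, 0.0, 0.30)  # improved, stable, declining
    age_log_hr: float = 0.06  # per year above 71
    diabetes_log_hr: float = 0.30
    cessation_prob_by_class: tuple = (0.15, 0.35, 0.25)
    cessation_max_years: float = 2.0

    @classmethod
    def zero(cls, baseline_hazard: float = 0.053) -> "DropoutLink":
        """A link with no class/group/covariate structure: death hazard is
        identical for everyone and series are never truncated before death."""
        return cls(
            baseline_hazard=baseline_hazard,
            class_log_hr=(0.0, 0.0, 0.0),
            age_log_hr=0.0,
            diabetes_log_hr=0.0,
            cessation_prob_by_class=(0.0, 0.0, 0.0),
        )

    @property
    def is_zero(self) -> bool:
        return (
            all(c == 0.0 for c in self.class_log_hr)
            and self.age_log_hr == 0.0
            and self.diabetes_log_hr == 0.0
            and all(c == 0.0 for c in self.cessation_prob_by_class)
        )


@dataclass(frozen=True)
class GeneratorConfig:
    n_patients: int = 4000
    slope_class_mix: tuple = (0.20, 0.55, 0.25)
    slope_means_by_class: tuple = (4.0, -0.4, -4.8)
    mean_intercept: float = 53.5
    random_effect_cov: tuple = ((12.25, 0.0), (0.0, 1.0))
    noise_dispersion: float = 0.3  # phi: Var(e) = phi * mean eGFR
    visits_per_year_rate: float = 2.0
    followup_years_pre: float = 5.0
    followup_years_post: float = 9.0
    dropout_link: DropoutLink = field(default_factory=DropoutLink)
    trajectory_groups: tuple = DEFAULT_TRAJECTORY_GROUPS
    post_t0_mode: str = "trajectory"  # or "continue": keep the pre-T0 line
    trajectory_offset_sd: float = 2.0  # patient-level intercept spread in a group
    death_year_egfr_offset: float = -5.0  # pattern-mixture offset (delta)
    covariate_prevalences: dict = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    covariate_class_logits: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_LOGITS)
    )
    female_fraction: float = 0.042
    race_mix: tuple = (0.876, 0.107, 0.017)  # white, black, other
    mean_age_at_cutover: float = 71.0
    sd_age: float = 8.0
    weight_available_fraction: float = 0.91
    uacr_available_fraction: float = 0.31
    emit_creatinine: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if abs(sum(self.slope_class_mix) - 1.0) > 1e-9:
            raise ValueError("slope_class_mix must sum to 1 within 1e-9")
        if self.noise_dispersion < 0:
            raise ValueError("noise_dispersion must be >= 0")
        if self.visits_per_year_rate <= 0:
            raise ValueError("visits_per_year_rate must be positive")
        if abs(sum(g.share for g in self.trajectory_groups) - 1.0) > 1e-9:
            raise ValueError("trajectory group shares must sum to 1")
        if self.post_t0_mode not in ("trajectory", "continue"):
            raise ValueError("post_t0_mode must be 'trajectory' or 'continue'")


@dataclass
class SyntheticCohort:
    """Analysis-facing measurement and patient tables plus a latent truth
    block kept separate so it never leaks into the analysis export."""

    measurements: pd.DataFrame  # patient_id, date, analyte, value
    patients: pd.DataFrame  # patient_id, birth_date, sex, race, death_date, flags
    truth: pd.DataFrame  # patient_id, true_class, true_intercept, ...
    config: GeneratorConfig


def _calibrate_class_intercepts(config: GeneratorConfig) -> np.ndarray:
    """Base multinomial-logit intercepts (improved, declining; stable = 0)
    such that the marginal class mix equals slope_class_mix despite the
    covariate-linked membership effects."""
    effects = config.covariate_class_logits
    target = np.asarray(config.slope_class_mix, dtype=float)
    if target[1] <= 0:
        raise ValueError("the stable class share must be positive")
    # classes with zero share are effectively removed from the logit model
    NEG = -1e3
    if not effects:
        with np.errstate(divide="ignore"):
            base = np.log(target[[0, 2]] / target[1])
        return np.where(np.isfinite(base), base, NEG)
    if target[0] == 0 or target[2] == 0:
        if target[0] == 0 and target[2] == 0:
            return np.array([NEG, NEG])
        # calibrate the remaining class alone (1-d bisection)
        free = 0 if target[0] > 0 else 2
        pos = 0 if free == 0 else 1

        def gap(b):
            base = np.array([NEG, NEG], dtype=float)
            base[pos] = b
            return _marginal_mix(base, config)[free] - target[free]

        b_star = optimize.brentq(gap, -20.0, 20.0, xtol=1e-12)
        base = np.array([NEG, NEG], dtype=float)
        base[pos] = b_star
        return base
    def marginal_gap(base):
        return _marginal_mix(base, config)[[0, 2]] - target[[0, 2]]

    start = np.log(target[[0, 2]] / target[1])
    sol = optimize.root(marginal_gap, start, tol=1e-12)
    if not sol.success:  # pragma: no cover - smooth 2-d problem
        raise RuntimeError("class-intercept calibration failed to converge")
    return sol.x


def _marginal_mix(base, config) -> np.ndarray:
    """Marginal class probabilities under independent-Bernoulli covariates."""
    effects = config.covariate_class_logits
    names = sorted(effects)
    if names:
        prev = np.array([config.covariate_prevalences[n] for n in names])
        combos = np.array(
            np.meshgrid(*[[0, 1]] * len(names), indexing="ij")
        ).reshape(len(names), -1).T
        combo_probs = np.prod(np.where(combos == 1, prev, 1 - prev), axis=1)
        shift = combos @ np.array([effects[n] for n in names])
    else:
        combo_probs = np.ones(1)
        shift = np.zeros((1, 2))
    logits = np.zeros((len(shift), 3))
    logits[:, 0] = base[0] + shift[:, 0]
    logits[:, 2] = base[1] + shift[:, 1]
    p = np.exp(logits - logits.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    return combo_probs @ p


def _class_probabilities(base, covariates, config) -> np.ndarray:
    logits = np.zeros((len(covariates), 3))
    logits[:, 0] = base[0]
    logits[:, 2] = base[1]
    for name, (d_imp, d_dec) in config.covariate_class_logits.items():
        x = covariates[name].to_numpy()
        logits[:, 0] += d_imp * x
        logits[:, 2] += d_dec * x
    p = np.exp(logits - logits.max(axis=1, keepdims=True))
    return p / p.sum(axis=1, keepdims=True)


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a seeded synthetic cohort.

    Each patient's pre-cutover eGFR at time t (years since their first
    visit) has mean a_i + b_i * t with (a_i, b_i) drawn around the latent
    class's slope mean; measurement noise is Normal(0, phi * mean) with the
    mean clipped below at 5 ml/min/1.73m^2 so the variance stays positive.
    Improved-class patients switch to their latent trajectory-group line
    after the cutover date (post_t0_mode="trajectory"); other classes
    continue their line.  Death times are exponential from the cutover with
    a log-linear hazard in class, trajectory group, age and diabetes;
    measurements after death (or after informative cessation) are deleted,
    and patients with a measurement in their year of death have the
    pattern-mixture offset added to their post-cutover means.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    meas_cols = ["patient_id", "date", "analyte", "value"]
    pat_cols = ["patient_id", "birth_date", "sex", "race", "death_date"] + list(
        COMORBIDITIES
    )
    truth_cols = [
        "patient_id",
        "true_class",
        "true_intercept",
        "true_slope",
        "true_group",
        "true_d",
    ]
    if n == 0:
        return SyntheticCohort(
            pd.DataFrame(columns=meas_cols),
            pd.DataFrame(columns=pat_cols),
            pd.DataFrame(columns=truth_cols),
            config,
        )

    ids = np.array([f"P{i:06d}" for i in range(1, n + 1)])

    # --- demographics and comorbidities -------------------------------
    age = np.clip(
        rng.normal(config.mean_age_at_cutover, config.sd_age, n), 45.0, 95.0
    )
    female = rng.random(n) < config.female_fraction
    race = rng.choice(["white", "black", "other"], size=n, p=config.race_mix)
    covariates = pd.DataFrame(
        {
            name: (rng.random(n) < p).astype(int)
            for name, p in (
                (c, config.covariate_prevalences.get(c, 0.0)) for c in COMORBIDITIES
            )
        }
    )

    # --- latent slope class and random effects ------------------------
    base = _calibrate_class_intercepts(config)
    probs = _class_probabilities(base, covariates, config)
    u = rng.random(n)
    cum = np.cumsum(probs, axis=1)
    class_idx = (u[:, None] > cum).sum(axis=1)
    class_means = np.column_stack(
        (
            np.full(n, config.mean_intercept),
            np.asarray(config.slope_means_by_class)[class_idx],
        )
    )
    cov = np.asarray(config.random_effect_cov, dtype=float)
    if np.any(np.diag(cov) < 0):
        raise ValueError("random_effect_cov variances must be non-negative")
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
    re = class_means + rng.standard_normal((n, 2)) @ chol.T
    a_i, b_i = re[:, 0], re[:, 1]

    # --- latent trajectory group (improved class only) ----------------
    shares = np.array([g.share for g in config.trajectory_groups])
    group_idx = np.where(
        class_idx == 0, rng.choice(len(shares), size=n, p=shares), -1
    )
    group_offsets = rng.normal(0.0, config.trajectory_offset_sd, n)

    # --- death model ---------------------------------------------------
    link = config.dropout_link
    log_h = (
        np.log(link.baseline_hazard)
        + np.asarray(link.class_log_hr)[class_idx]
        + link.age_log_hr * (age - config.mean_age_at_cutover)
        + link.diabetes_log_hr * covariates["diabetes"].to_numpy()
    )
    group_lhr = np.array([g.log_hr for g in config.trajectory_groups])
    log_h = log_h + np.where(group_idx >= 0, group_lhr[np.maximum(group_idx, 0)], 0.0)
    t_death = rng.exponential(1.0 / np.exp(log_h))  # years from cutover
    dies_in_study = t_death < config.followup_years_post
    cess_prob = np.asarray(link.cessation_prob_by_class)[class_idx]
    ceases = dies_in_study & (rng.random(n) < cess_prob)
    t_cease = np.where(
        ceases,
        t_death - rng.uniform(0.0, link.cessation_max_years, n),
        np.inf,
    )

    # --- per-patient visit schedules -----------------------------------
    first_visit_span = (FIRST_VISIT_END - PRE_WINDOW_START).days
    total_span_years = (STUDY_END - PRE_WINDOW_START).days / DAYS_PER_YEAR
    cutover_years = (CUTOVER_DATE - PRE_WINDOW_START).days / DAYS_PER_YEAR

    meas_rows: list[tuple] = []
    truth_d = np.zeros(n, dtype=int)
    death_dates: list = []
    has_weight = rng.random(n) < config.weight_available_fraction
    has_uacr = rng.random(n) < config.uacr_available_fraction
    weight0 = rng.normal(190.0, 30.0, n)
    weight_trend = rng.normal(-0.6, 5.0, n)
    uacr_shift = np.array([-0.15, 0.0, 0.45])[class_idx]
    uacr_value = np.exp(rng.normal(2.7 + uacr_shift, 2.0))

    groups = config.trajectory_groups
    phi = config.noise_dispersion

    for i in range(n):
        t_first = rng.uniform(0.0, first_visit_span) / DAYS_PER_YEAR
        end_i = min(total_span_years, cutover_years + t_death[i])
        # Poisson-process visit times (years since window start), preceded by
        # a guideline-style confirmatory re-test 3-6 months after the first
        # abnormal eGFR (the 90-day-separation inclusion rule presupposes one)
        t_confirm = t_first + rng.uniform(91.0, 180.0) / DAYS_PER_YEAR
        times = [t_first]
        if t_confirm < end_i:
            times.append(t_confirm)
        t = t_confirm
        while True:
            t = t + rng.exponential(1.0 / config.visits_per_year_rate)
            if t >= end_i:
                break
            times.append(t)
        times = np.asarray(times)
        # informative cessation truncates the tail, but each patient keeps
        # at least their first two visits so the series stays analysable
        if np.isfinite(t_cease[i]):
            keep = times < cutover_years + t_cease[i]
            keep[: min(2, len(times))] = True
            times = times[keep]
        # distinct calendar days only (duplicate lab rows are an input error
        # downstream)
        days = np.unique(np.round(times * DAYS_PER_YEAR).astype(int))
        times = days / DAYS_PER_YEAR
        t_first = times[0]  # keep the line anchored on the emitted first date

        # pattern-mixture indicator: an eGFR measurement in the year of death
        if dies_in_study[i]:
            death_year = int(np.floor(t_death[i]))
            post = times - cutover_years
            truth_d[i] = int(
                np.any((post >= 0) & (np.floor(post) == death_year))
            )
            death_dates.append(
                CUTOVER_DATE + pd.Timedelta(days=round(t_death[i] * DAYS_PER_YEAR))
            )
        else:
            death_dates.append(pd.NaT)

        # mean eGFR on each visit day
        pre = times < cutover_years
        mu = a_i[i] + b_i[i] * (times - t_first)
        if config.post_t0_mode == "trajectory" and group_idx[i] >= 0:
            g = groups[group_idx[i]]
            mu_post = (
                g.intercept
                + g.slope * (times - cutover_years)
                + group_offsets[i]
            )
            mu = np.where(pre, mu, mu_post)
        if truth_d[i]:
            mu = np.where(pre, mu, mu + config.death_year_egfr_offset)
        mu_clip = np.maximum(mu, EGFR_FLOOR)
        egfr = mu + rng.standard_normal(len(mu)) * np.sqrt(phi * mu_clip)
        egfr = np.maximum(egfr, 2.0)  # lab floor; keeps values positive

        dates = PRE_WINDOW_START + pd.to_timedelta(days, unit="D")
        if config.emit_creatinine:
            age_at = age[i] + (times - cutover_years)
            scr = inverse_ckd_epi_creatinine(
                egfr, np.maximum(age_at, 18.0), female[i], race[i] == "black"
            )
            for d, v in zip(dates, np.atleast_1d(scr)):
                meas_rows.append((ids[i], d, "creatinine_mg_dl", round(v, 4)))
        else:
            for d, v in zip(dates, egfr):
                meas_rows.append((ids[i], d, "egfr", round(v, 3)))

        if has_weight[i]:
            pre_days = days[pre]
            w_days = pre_days[::2] if len(pre_days) >= 2 else pre_days
            for d in w_days:
                t_w = d / DAYS_PER_YEAR
                w = weight0[i] + weight_trend[i] * t_w + rng.normal(0.0, 3.0)
                meas_rows.append(
                    (
                        ids[i],
                        PRE_WINDOW_START + pd.Timedelta(days=int(d)),
                        "weight_lb",
                        round(max(w, 80.0), 1),
                    )
                )
        if has_uacr[i] and pre.any():
            d = int(rng.choice(days[pre]))
            meas_rows.append(
                (
                    ids[i],
                    PRE_WINDOW_START + pd.Timedelta(days=d),
                    "uacr_mg_g",
                    round(uacr_value[i], 1),
                )
            )

    measurements = pd.DataFrame(meas_rows, columns=meas_cols)
    measurements = measurements.sort_values(
        ["patient_id", "date", "analyte"], kind="mergesort"
    ).reset_index(drop=True)

    birth_dates = CUTOVER_DATE - pd.to_timedelta(
        np.round(age * DAYS_PER_YEAR).astype(int), unit="D"
    )
    patients = pd.DataFrame(
        {
            "patient_id": ids,
            "birth_date": birth_dates,
            "sex": np.where(female, "F", "M"),
            "race": race,
            "death_date": death_dates,
        }
    )
    for c in COMORBIDITIES:
        patients[c] = covariates[c].to_numpy()

    truth = pd.DataFrame(
        {
            "patient_id": ids,
            "true_class": np.asarray(CLASS_NAMES)[class_idx],
            "true_intercept": a_i,
            "true_slope": b_i,
            "true_group": group_idx,
            "true_d": truth_d,
        }
    )
    return SyntheticCohort(measurements, patients, truth, config)


# ---------------------------------------------------------------------------
# export / import

def export_cohort(cohort: SyntheticCohort, path) -> dict:
    """Write measurements.csv and patients.csv (analysis-facing) plus
    truth.csv (test-only, separate file).  Returns the file paths."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = {}
    m = cohort.measurements.copy()
    m["date"] = pd.to_datetime(m["date"]).dt.strftime("%Y-%m-%d")
    files["measurements"] = path / "measurements.csv"
    m.to_csv(files["measurements"], index=False)

    p = cohort.patients.copy()
    for c in ("birth_date", "death_date"):
        p[c] = pd.to_datetime(p[c]).dt.strftime("%Y-%m-%d")
    p["death_date"] = p["death_date"].fillna("")
    files["patients"] = path / "patients.csv"
    p.to_csv(files["patients"], index=False)

    files["truth"] = path / "truth.csv"
    cohort.truth.to_csv(files["truth"], index=False)
    return files


def load_cohort(path) -> SyntheticCohort:
    """Re-import an exported cohort (lossless for analysis-facing fields)."""
    path = Path(path)
    m = pd.read_csv(path / "measurements.csv", parse_dates=["date"])
    p = pd.read_csv(
        path / "patients.csv", parse_dates=["birth_date", "death_date"]
    )
    truth_file = path / "truth.csv"
    truth = pd.read_csv(truth_file) if truth_file.exists() else pd.DataFrame()
    return SyntheticCohort(m, p, truth, None)


# ---------------------------------------------------------------------------
# direct annual-panel generator for the trajectory model

def generate_annual_panel(
    n_patients: int,
    groups,
    sigma: float = 3.0,
    delta: float = 0.0,
    d_prob: float = 0.0,
    patient_offset_sd: float = 0.0,
    n_years: int = 9,
    dropout_hazard: float = 0.0,
    mean_measurements: float = 1.5,
    seed: int = 0,
):
    """Annual-average eGFR panel with planted trajectory groups.

    Used to exercise the latent trajectory model in isolation.  ``groups``
    is a sequence of (share, intercept, slope) triples; each patient's
    annual mean in group k is intercept_k + slope_k * year + offset_i +
    delta * d_i + Normal(0, sigma), where d_i ~ Bernoulli(d_prob) is the
    death-year-measurement indicator.  ``dropout_hazard`` truncates series
    geometrically (probability per year of being the last observed year).

    Returns (annual DataFrame, d indicator Series, true group Series).
    """
    rng = np.random.default_rng(seed)
    shares = np.array([g[0] for g in groups])
    if abs(shares.sum() - 1.0) > 1e-9:
        raise ValueError("group shares must sum to 1")
    intercepts = np.array([g[1] for g in groups])
    slopes = np.array([g[2] for g in groups])
    gidx = rng.choice(len(groups), size=n_patients, p=shares)
    d = (rng.random(n_patients) < d_prob).astype(int)
    offsets = rng.normal(0.0, patient_offset_sd, n_patients)

    rows = []
    ids = [f"S{i:05d}" for i in range(1, n_patients + 1)]
    for i in range(n_patients):
        last_year = n_years - 1
        if dropout_hazard > 0:
            g_draw = rng.geometric(dropout_hazard)
            last_year = min(n_years - 1, int(g_draw))
        for year in range(last_year + 1):
            mean = (
                intercepts[gidx[i]]
                + slopes[gidx[i]] * year
                + offsets[i]
                + delta * d[i]
            )
            y = mean + rng.normal(0.0, sigma)
            n_meas = 1 + rng.poisson(mean_measurements)
            rows.append((ids[i], year, y, n_meas))
    annual = pd.DataFrame(
        rows, columns=["patient_id", "year_index", "mean_egfr", "n_measurements"]
    )
    d_series = pd.Series(d, index=ids, name="death_year_measurement")
    true_group = pd.Series(gidx, index=ids, name="true_group")
    return annual, d_series, true_group


def config_to_dict(config: GeneratorConfig) -> dict:
    """Plain-dict view of a config (for logging / report provenance)."""
    return dataclasses.asdict(config)
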