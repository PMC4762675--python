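"""Adjusted mortality and class-membership models.

Cox proportional-hazards models of death at 1/3/5/9-year horizons (follow-up
administratively truncated at the horizon), multinomial logistic models of
slope-class / phenotype membership, and Wald tests of exposure-by-albuminuria
interactions.  Estimation is delegated to statsmodels (PHReg with Breslow or
Efron ties; MNLogit for the multinomial); the surrounding covariate handling,
horizon truncation and reporting live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import COMORBIDITIES

__all__ = [
    "ModelSpec",
    "FitResult",
    "fit_cox",
    "fit_multinomial",
    "test_interaction",
    "build_report",
]

#: Fully adjusted covariate set: demographics, the ten comorbidity flags and
#: eGFR at cohort entry.
DEFAULT_COVARIATES = (
    "age_at_t0",
    "race",
    "sex",
    *COMORBIDITIES,
    "t0_egfr",
)


@dataclass(frozen=True)
class ModelSpec:
    outcome_horizon: float = 9.0  # years
    covariates: tuple = DEFAULT_COVARIATES
    exposure: str | None = "slope_class"  # None: covariates-only model
    reference: str = "stable"
    include_weight_change: bool = False
    include_albuminuria: bool = False
    interaction_with_albuminuria: bool = False
    ties_method: str = "breslow"  # or "efron"
    horizon_method: str = "truncate"  # or "landmark"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.outcome_horizon <= 0:
            raise ValueError("outcome_horizon must be positive")
        if self.ties_method not in ("breslow", "efron"):
            raise ValueError("ties_method must be 'breslow' or 'efron'")
        if self.horizon_method not in ("truncate", "landmark"):
            raise ValueError("horizon_method must be 'truncate' or 'landmark'")


@dataclass
class FitResult:
    """Estimates on the log scale with exponentiated CIs for reporting.
    A term is 'significant' when its 95% CI excludes 1."""

    terms: pd.DataFrame  # term, coef, se, ratio, ci_low, ci_high, p, significant
    n: int
    events: int | None
    converged: bool
    model: str
    warning: str | None = None


def _dummies(df: pd.DataFrame, col: str, reference: str) -> pd.DataFrame:
    levels = [l for l in pd.unique(df[col].dropna()) if l != reference]
    out = pd.DataFrame(index=df.index)
    for level in sorted(map(str, levels)):
        out[f"{col}[{level}]"] = (df[col].astype(str) == level).astype(float)
    return out


def _design(cohort: pd.DataFrame, spec: ModelSpec, with_exposure=True):
    """Covariate design frame (complete-case over the columns used)."""
    df = cohort.copy()
    X = pd.DataFrame(index=df.index)
    for cov in spec.covariates:
        if cov == "race":
            X = X.join(_dummies(df, "race", "white"))
        elif cov == "sex":
            X["female"] = (df["sex"] == "F").astype(float)
        elif cov in df.columns:
            X[cov] = pd.to_numeric(df[cov], errors="coerce")
    if spec.include_weight_change:
        X["annual_pct_weight_change"] = df["annual_pct_weight_change"]
    if spec.include_albuminuria:
        X = X.join(_dummies(df, "albuminuria_category", "normal"))
        X.loc[df["albuminuria_category"].isna(), X.filter(
            regex=r"albuminuria_category"
        ).columns] = np.nan
    expo_cols = []
    if with_exposure and spec.exposure is not None:
        expo = _dummies(df, spec.exposure, spec.reference)
        expo.loc[df[spec.exposure].isna(), expo.columns] = np.nan
        expo_cols = list(expo.columns)
        X = X.join(expo)
    if spec.interaction_with_albuminuria:
        if not spec.include_albuminuria:
            raise ValueError("interaction requires include_albuminuria")
        alb_cols = [c for c in X.columns if c.startswith("albuminuria_category")]
        alb_levels = len(pd.unique(cohort["albuminuria_category"].dropna()))
        if alb_levels < 2:
            raise ValueError("albuminuria has a single level; interaction undefined")
        for e in expo_cols:
            for a in alb_cols:
                X[f"{e}:{a}"] = X[e] * X[a]
    return X, expo_cols


def _terms_frame(names, coefs, ses, alpha: float) -> pd.DataFrame:
    z = stats.norm.ppf(1 - alpha / 2)
    coefs = np.asarray(coefs, float)
    ses = np.asarray(ses, float)
    ci_low = np.exp(coefs - z * ses)
    ci_high = np.exp(coefs + z * ses)
    pvals = 2 * stats.norm.sf(np.abs(coefs / ses))
    return pd.DataFrame(
        {
            "term": names,
            "coef": coefs,
            "se": ses,
            "ratio": np.exp(coefs),
            "ci_low": ci_low,
            "ci_high": ci_high,
            "p": pvals,
            "significant": (ci_low > 1.0) | (ci_high < 1.0),
        }
    )


def _horizon_data(cohort: pd.DataFrame, spec: ModelSpec):
    h = spec.outcome_horizon
    t = cohort["followup_time"].astype(float)
    e = cohort["death_flag"].astype(int)
    if spec.horizon_method == "landmark":
        keep = (t >= h) | (e == 1)
        t, e = t[keep], e[keep]
        cohort = cohort.loc[keep]
    event = ((e == 1) & (t <= h)).astype(int)
    duration = np.minimum(t, h)
    return cohort, duration, event


def fit_cox(cohort: pd.DataFrame, spec: ModelSpec = ModelSpec(), _cov=False):
    """Cox proportional-hazards model of death within the horizon.

    Deaths after the horizon are administratively censored at the horizon.
    The partial likelihood (Breslow or Efron ties) is maximised by Newton
    iteration via statsmodels PHReg.  Returns a :class:`FitResult` (and the
    coefficient covariance when ``_cov`` is set, for Wald interaction tests).
    """
    import statsmodels.api as sm

    cohort, duration, event = _horizon_data(cohort, spec)
    X, _ = _design(cohort, spec)
    data = X.copy()
    data["duration"] = np.asarray(duration, float)
    data["event"] = np.asarray(event, int)
    data = data.dropna()
    n = len(data)
    events = int(data["event"].sum())
    if events == 0:
        raise ValueError("no death events within the horizon")

    warning = None
    names = list(data.drop(columns=["duration", "event"]).columns)
    mod = sm.PHReg(
        data["duration"],
        data[names],
        status=data["event"],
        ties=spec.ties_method,
    )
    res = None
    err_msg = None
    for method in ("newton", "lbfgs"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = mod.fit(method=method, disp=False)
            if np.all(np.isfinite(res.params)) and np.all(np.isfinite(res.bse)):
                break
        except Exception as err:  # singular Hessian etc.: try the fallback
            err_msg = str(err)
            res = None
    if res is None:  # convergence failure is flagged, not silent
        return FitResult(
            terms=pd.DataFrame(columns=["term", "coef", "se", "ratio",
                                        "ci_low", "ci_high", "p", "significant"]),
            n=n,
            events=events,
            converged=False,
            model="cox",
            warning=err_msg or "optimisation failed",
        )
    coefs = np.asarray(res.params)
    ses = np.asarray(res.bse)
    cov = np.asarray(res.cov_params())
    converged = bool(np.all(np.isfinite(coefs)) and np.all(np.isfinite(ses)))

    terms = _terms_frame(names, coefs, ses, spec.alpha)
    big = terms.loc[np.abs(terms["coef"]) > 10, "term"].tolist()
    if big:
        warning = f"possibly unstable coefficients: {big}"
    result = FitResult(
        terms=terms,
        n=n,
        events=events,
        converged=converged,
        model="cox",
        warning=warning,
    )
    if _cov:
        return result, pd.DataFrame(cov, index=names, columns=names)
    return result


def fit_multinomial(cohort: pd.DataFrame, spec: ModelSpec = ModelSpec()):
    """Maximum-likelihood multinomial logit of the exposure class on the
    covariates, odds ratios per non-reference level vs the reference."""
    import statsmodels.api as sm

    levels = sorted(map(str, pd.unique(cohort[spec.exposure].dropna())))
    if spec.reference not in levels:
        raise ValueError(f"reference level {spec.reference!r} not present")
    if len(levels) < 2:
        raise ValueError("exposure must have at least 2 levels")
    order = [spec.reference] + [l for l in levels if l != spec.reference]
    codes = cohort[spec.exposure].astype(str).map(
        {l: i for i, l in enumerate(order)}
    )
    X, _ = _design(cohort, spec, with_exposure=False)
    X = sm.add_constant(X)
    mask = X.notna().all(axis=1) & codes.notna()
    Xm, ym = X[mask], codes[mask].astype(int)

    warning = None
    try:
        res = sm.MNLogit(ym, Xm).fit(method="newton", maxiter=200, disp=False)
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception as err:
        return FitResult(
            terms=pd.DataFrame(),
            n=int(mask.sum()),
            events=None,
            converged=False,
            model="multinomial",
            warning=str(err),
        )
    rows = []
    params = np.asarray(res.params)  # (k_vars, J-1)
    bse = np.asarray(res.bse)
    for j, level in enumerate(order[1:]):
        for i, name in enumerate(Xm.columns):
            rows.append((f"{level}: {name}", params[i, j], bse[i, j]))
    names, coefs, ses = zip(*rows)
    terms = _terms_frame(list(names), coefs, ses, spec.alpha)
    big = terms.loc[np.abs(terms["coef"]) > 10, "term"].tolist()
    if big:
        converged = False
        warning = f"possible complete separation in terms: {big}"
    return FitResult(
        terms=terms,
        n=int(mask.sum()),
        events=None,
        converged=converged,
        model="multinomial",
        warning=warning,
    )


def test_interaction(cohort: pd.DataFrame, spec: ModelSpec):
    """Wald tests of exposure-by-albuminuria product terms in the Cox model.

    Returns a DataFrame of per-product-term Wald p-values plus a joint Wald
    chi-square row across all product terms.
    """
    if not spec.interaction_with_albuminuria:
        spec = ModelSpec(
            **{
                **spec.__dict__,
                "include_albuminuria": True,
                "interaction_with_albuminuria": True,
            }
        )
    result, cov = fit_cox(cohort, spec, _cov=True)
    if not result.converged:
        raise RuntimeError(f"interaction model did not converge: {result.warning}")
    prod = result.terms[result.terms["term"].str.contains(":")]
    if prod.empty:
        raise ValueError("no product terms present; check level combinations")
    rows = [
        {"term": r.term, "wald_chi2": (r.coef / r.se) ** 2, "p": r.p}
        for r in prod.itertuples()
    ]
    beta = prod["coef"].to_numpy()
    V = cov.loc[prod["term"], prod["term"]].to_numpy()
    chi2 = float(beta @ np.linalg.solve(V, beta))
    rows.append(
        {
            "term": "(joint)",
            "wald_chi2": chi2,
            "p": float(stats.chi2.sf(chi2, df=len(beta))),
        }
    )
    return pd.DataFrame(rows)


def _descriptives(cohort: pd.DataFrame, by: str) -> dict:
    out = {}
    for level, grp in cohort.groupby(by):
        out[str(level)] = {
            "n": int(len(grp)),
            "share": float(len(grp) / len(cohort)),
            "age_mean": float(grp["age_at_t0"].mean()),
            "deaths": int(grp["death_flag"].sum()),
            "death_pct": float(100.0 * grp["death_flag"].mean()),
            "initial_egfr_mean": float(grp["initial_egfr"].mean()),
            "t0_egfr_mean": float(grp["t0_egfr"].mean()),
            "median_n_egfr_pre_t0": float(grp["n_egfr_pre_t0"].median()),
        }
    return out


def build_report(
    cohort: pd.DataFrame,
    slope_table: pd.DataFrame,
    cox_fits: dict,
    multinomial_fit: FitResult | None = None,
    trajectory_ladder: pd.DataFrame | None = None,
    group_summaries: pd.DataFrame | None = None,
    phenotype_labels: pd.DataFrame | None = None,
    phenotype_cox_fits: dict | None = None,
) -> dict:
    """Assemble the structured end-of-pipeline report.

    ``cox_fits`` / ``phenotype_cox_fits`` map horizon (years) -> FitResult.
    All entries are plain types so the report serialises to JSON and
    regenerates byte-identically from persisted intermediates.
    """
    merged = cohort.merge(slope_table, on="patient_id", how="left")
    report: dict = {
        "cohort": {
            "n": int(len(cohort)),
            "deaths": int(cohort["death_flag"].sum()),
        },
        "slope_classes": _descriptives(merged, "slope_class"),
        "hazard_ratios_by_class": {},
    }
    for h, fit in sorted(cox_fits.items()):
        if not fit.converged or fit.terms.empty:
            report["hazard_ratios_by_class"][str(h)] = {
                "not_converged": fit.warning or "optimisation failed"
            }
            continue
        rows = fit.terms[fit.terms["term"].str.startswith("slope_class")]
        report["hazard_ratios_by_class"][str(h)] = {
            r.term: {
                "hr": round(r.ratio, 4),
                "ci": [round(r.ci_low, 4), round(r.ci_high, 4)],
            }
            for r in rows.itertuples()
        }
    if multinomial_fit is not None and multinomial_fit.converged:
        report["class_odds_ratios"] = {
            r.term: {
                "or": round(r.ratio, 4),
                "ci": [round(r.ci_low, 4), round(r.ci_high, 4)],
            }
            for r in multinomial_fit.terms.itertuples()
        }
    if trajectory_ladder is None or group_summaries is None:
        report["trajectory"] = {"skipped": True, "reason": "no improved subcohort"}
    else:
        report["trajectory"] = {
            "skipped": False,
            "ladder": trajectory_ladder.round(4).to_dict(orient="records"),
            "groups": group_summaries.round(4).to_dict(orient="records"),
        }
        if phenotype_labels is not None:
            report["phenotypes"] = phenotype_labels.round(4).to_dict(
                orient="records"
            )
        if phenotype_cox_fits:
            report["hazard_ratios_by_phenotype"] = {}
            for h, fit in sorted(phenotype_cox_fits.items()):
                if not fit.converged or fit.terms.empty:
                    report["hazard_ratios_by_phenotype"][str(h)] = {
                        "not_converged": fit.warning or "optimisation failed"
                    }
                    continue
                rows = fit.terms[fit.terms["term"].str.startswith("phenotype")]
                report["hazard_ratios_by_phenotype"][str(h)] = {
                    r.term: {
                        "hr": round(r.ratio, 4),
                        "ci": [round(r.ci_low, 4), round(r.ci_high, 4)],
                    }
                    for r in rows.itertuples()
                }
    return report
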