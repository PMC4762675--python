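"""Hierarchical Bayesian mixed-effects eGFR slope model and classification.

Model, for patient i with eGFR y_ij at time t_ij (years since the patient's
initial eGFR):

    y_ij ~ Normal(a_i + b_i t_ij,  phi * max(mu_ij, 5))
    (a_i, b_i) ~ BivariateNormal(m, Sigma)
    m_k ~ Normal(m0_k, s0_k^2),  Sigma^-1 ~ Wishart(nu, R),
    phi ~ InverseGamma(a, b)

The residual variance is proportional to the mean eGFR level (clipped below
at 5 ml/min/1.73m^2 so it stays positive).  Because the mean enters the
variance, the per-patient random effects are updated by adaptive random-walk
Metropolis; m, Sigma and phi remain conditionally conjugate and use Gibbs
updates.  Patients are classified from the kept draws: improved when
P(b_i > 0) > 0.95, declining when P(b_i < -1) > 0.95, stable otherwise.

Ordinary least squares per-patient slopes are provided as the comparator
that overstates the positive-slope fraction on noisy data; the Bayesian
estimates shrink toward the population mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .egfr_core import EGFR_FLOOR

__all__ = [
    "SlopeModelSpec",
    "SlopePosterior",
    "SlopeFit",
    "fit_hierarchical_model",
    "classify_slope",
    "ols_slope",
]


@dataclass(frozen=True)
class SlopeModelSpec:
    n_iterations: int = 5000  # kept MCMC draws
    burn_in: int = 1000  # discarded, additional to the kept draws
    hyperprior_mean: tuple = (53.0, 0.0)  # m0 for (intercept, slope)
    hyperprior_sd: tuple = (20.0, 5.0)  # s0
    wishart_df: float = 3.0
    wishart_scale: tuple = ((100.0, 0.0), (0.0, 10.0))
    dispersion_prior: tuple = (2.0, 2.0)  # InvGamma(a, b) on phi
    improved_threshold: float = 0.0
    declining_threshold: float = -1.0
    posterior_prob: float = 0.95
    variance_mode: str = "proportional"  # or "fixed" (homoscedastic, known)
    fixed_variance: float = 25.0
    variance_mean: str = "fitted"  # or "patient_average"
    adapt_interval: int = 50
    target_acceptance: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wishart_df < 2:
            raise ValueError("wishart_df must be >= 2 for a 2x2 scale")
        if self.variance_mode not in ("proportional", "fixed"):
            raise ValueError("variance_mode must be 'proportional' or 'fixed'")
        if self.variance_mean not in ("fitted", "patient_average"):
            raise ValueError("variance_mean must be 'fitted' or 'patient_average'")
        if not 0 < self.posterior_prob < 1:
            raise ValueError("posterior_prob must be in (0, 1)")


@dataclass
class SlopePosterior:
    """Kept MCMC draws and classification for one patient."""

    patient_id: str
    draws_slope: np.ndarray
    draws_intercept: np.ndarray
    posterior_mean_slope: float
    p_gt_0: float
    p_lt_neg1: float
    slope_class: str


@dataclass
class SlopeFit:
    """Fitted hierarchical model: per-patient posteriors plus the population
    posterior (m, Sigma, phi) and chain diagnostics."""

    patient_ids: np.ndarray
    draws_intercept: np.ndarray  # (n_kept, n_patients), float32
    draws_slope: np.ndarray
    draws_m: np.ndarray  # (n_kept, 2)
    draws_sigma: np.ndarray  # (n_kept, 3): s_aa, s_ab, s_bb
    draws_phi: np.ndarray
    p_gt_0: np.ndarray
    p_lt_neg1: np.ndarray
    classes: np.ndarray
    acceptance_rate: np.ndarray
    spec: SlopeModelSpec

    @property
    def posterior_mean_slope(self) -> np.ndarray:
        return self.draws_slope.mean(axis=0).astype(float)

    def posterior(self, patient_id) -> SlopePosterior:
        i = int(np.flatnonzero(self.patient_ids == patient_id)[0])
        return SlopePosterior(
            patient_id=patient_id,
            draws_slope=self.draws_slope[:, i].astype(float),
            draws_intercept=self.draws_intercept[:, i].astype(float),
            posterior_mean_slope=float(self.draws_slope[:, i].mean()),
            p_gt_0=float(self.p_gt_0[i]),
            p_lt_neg1=float(self.p_lt_neg1[i]),
            slope_class=str(self.classes[i]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "posterior_mean_slope": self.posterior_mean_slope,
                "p_gt_0": self.p_gt_0,
                "p_lt_neg1": self.p_lt_neg1,
                "slope_class": self.classes,
            }
        )

    def split_rhat(self) -> dict:
        """Split-chain R-hat for the population parameters."""
        out = {}
        for name, x in (
            ("m_intercept", self.draws_m[:, 0]),
            ("m_slope", self.draws_m[:, 1]),
            ("phi", self.draws_phi),
        ):
            out[name] = _split_rhat(np.asarray(x, dtype=float))
        return out


def _split_rhat(x: np.ndarray) -> float:
    n = len(x) // 2
    halves = np.stack([x[:n], x[n : 2 * n]])
    w = halves.var(axis=1, ddof=1).mean()
    b = n * halves.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0
    return float(np.sqrt((n - 1) / n + b / (w * n)))


def _prepare(points: pd.DataFrame):
    df = points[["patient_id", "time", "egfr"]].copy()
    if not np.all(np.isfinite(df["egfr"])) or not np.all(np.isfinite(df["time"])):
        bad = df.loc[
            ~np.isfinite(df["egfr"]) | ~np.isfinite(df["time"]), "patient_id"
        ].iloc[0]
        raise ValueError(f"non-finite eGFR or time for patient {bad}")
    df = df.sort_values(["patient_id", "time"], kind="mergesort")
    ids, idx = np.unique(df["patient_id"].to_numpy(), return_inverse=True)
    t = df["time"].to_numpy(float)
    y = df["egfr"].to_numpy(float)
    n_per = np.bincount(idx)
    if np.any(n_per < 2):
        raise ValueError(
            f"patient {ids[np.argmin(n_per)]} has fewer than 2 eGFR points"
        )
    # distinct times within patient
    tmin = np.full(len(ids), np.inf)
    tmax = np.full(len(ids), -np.inf)
    np.minimum.at(tmin, idx, t)
    np.maximum.at(tmax, idx, t)
    if np.any(tmax - tmin <= 0):
        raise ValueError(
            f"patient {ids[np.argmin(tmax - tmin)]} has all measurements at one time"
        )
    return ids, idx, t, y, n_per


def ols_slope(points: pd.DataFrame) -> pd.DataFrame:
    """Per-patient ordinary least-squares slope of eGFR on time."""
    ids, idx, t, y, n_per = _prepare(points)
    st = np.bincount(idx, weights=t)
    sy = np.bincount(idx, weights=y)
    stt = np.bincount(idx, weights=t * t)
    sty = np.bincount(idx, weights=t * y)
    denom = stt - st * st / n_per
    slope = (sty - st * sy / n_per) / denom
    intercept = (sy - slope * st) / n_per
    return pd.DataFrame(
        {
            "patient_id": ids,
            "ols_slope": slope,
            "ols_intercept": intercept,
            "n_points": n_per,
        }
    )


def classify_slope(p_gt_0, p_lt_neg1, spec: SlopeModelSpec = SlopeModelSpec()):
    """Posterior-probability classification rule (strict inequalities).

    improved  iff P(b > improved_threshold) > posterior_prob
    declining iff P(b < declining_threshold) > posterior_prob
    stable otherwise.  Both conditions holding simultaneously is impossible
    for disjoint events at probability > 0.5; it is asserted, not resolved.
    """
    p_gt_0 = np.asarray(p_gt_0, dtype=float)
    p_lt_neg1 = np.asarray(p_lt_neg1, dtype=float)
    improved = p_gt_0 > spec.posterior_prob
    declining = p_lt_neg1 > spec.posterior_prob
    if np.any(improved & declining):
        raise RuntimeError(
            "classification rule produced both improved and declining; "
            "draw fractions of disjoint events exceed 100%"
        )
    out = np.where(improved, "improved", np.where(declining, "declining", "stable"))
    if out.ndim == 0:
        return str(out)
    return out


def _inv2(s: np.ndarray) -> np.ndarray:
    det = s[0, 0] * s[1, 1] - s[0, 1] * s[1, 0]
    return np.array([[s[1, 1], -s[0, 1]], [-s[1, 0], s[0, 0]]]) / det


def _wishart_2x2(rng, df: float, scale: np.ndarray) -> np.ndarray:
    # Bartlett decomposition
    L = np.linalg.cholesky(scale)
    A = np.zeros((2, 2))
    A[0, 0] = np.sqrt(rng.chisquare(df))
    A[1, 1] = np.sqrt(rng.chisquare(df - 1))
    A[1, 0] = rng.standard_normal()
    LA = L @ A
    return LA @ LA.T


def fit_hierarchical_model(
    points: pd.DataFrame, spec: SlopeModelSpec = SlopeModelSpec()
) -> SlopeFit:
    """Fit the three-level hierarchical model by Metropolis-within-Gibbs.

    ``points`` holds columns patient_id, time (years since the patient's
    initial eGFR) and egfr.  Returns a :class:`SlopeFit` with the kept draws
    (burn-in discarded), classification, acceptance rates and the population
    posterior.  The chain is deterministic given ``spec.seed``.
    """
    ids, idx, t, y, n_per = _prepare(points)
    n = len(ids)
    rng = np.random.default_rng(spec.seed)

    # --- initial values from per-patient OLS -------------------------
    ols = ols_slope(points)
    a = ols["ols_intercept"].to_numpy().copy()
    b = ols["ols_slope"].to_numpy().copy()
    m = np.array([a.mean(), b.mean()])
    u = np.column_stack([a, b])
    if n > 1:
        sigma = np.cov(u.T) + 1e-3 * np.eye(2)
    else:
        sigma = np.diag([10.0, 2.0])
    if not np.all(np.isfinite(sigma)):
        sigma = np.diag([10.0, 2.0])

    fixed_var = spec.variance_mode == "fixed"
    patient_avg = spec.variance_mean == "patient_average"
    if patient_avg:
        ybar = np.bincount(idx, weights=y) / n_per
        w_const = np.maximum(ybar, EGFR_FLOOR)[idx]

    def weights_of(a_vec, b_vec):
        """Per-point variance weight w: Var = phi * w."""
        if fixed_var:
            return np.full(len(y), spec.fixed_variance)
        if patient_avg:
            return w_const
        mu = a_vec[idx] + b_vec[idx] * t
        return np.maximum(mu, EGFR_FLOOR)

    def suffstats(a_vec, b_vec):
        """Per-patient A_i = sum log w, S_i = sum r^2 / w."""
        w = weights_of(a_vec, b_vec)
        r = y - (a_vec[idx] + b_vec[idx] * t)
        return (
            np.bincount(idx, weights=np.log(w)),
            np.bincount(idx, weights=r * r / w),
        )

    A_cur, S_cur = suffstats(a, b)
    if fixed_var:
        phi = 1.0
    else:
        phi = max(float(np.median(S_cur / n_per)), 1e-3)

    # random-walk proposal scales from the OLS design
    st = np.bincount(idx, weights=t)
    stt = np.bincount(idx, weights=t * t)
    tbar = st / n_per
    sxx = np.maximum(stt - n_per * tbar**2, 1e-6)
    base_sd_b = np.sqrt(phi * np.maximum(a, EGFR_FLOOR) / sxx)
    base_sd_a = base_sd_b * np.sqrt(stt / n_per)
    scale = np.ones(n)

    s0 = np.asarray(spec.hyperprior_sd, dtype=float)
    m0 = np.asarray(spec.hyperprior_mean, dtype=float)
    prior_prec_m = np.diag(1.0 / s0**2)
    R = np.asarray(spec.wishart_scale, dtype=float)
    R_inv = _inv2(R)
    ig_a, ig_b = spec.dispersion_prior
    N_total = len(y)

    n_kept = spec.n_iterations
    total = spec.burn_in + n_kept
    draws_a = np.empty((n_kept, n), dtype=np.float32)
    draws_b = np.empty((n_kept, n), dtype=np.float32)
    draws_m = np.empty((n_kept, 2))
    draws_sigma = np.empty((n_kept, 3))
    draws_phi = np.empty(n_kept)
    accepts = np.zeros(n)
    window_accepts = np.zeros(n)

    sigma_inv = _inv2(sigma)

    for it in range(total):
        # --- Metropolis update of (a_i, b_i), vectorised over patients
        prop_a = a + scale * base_sd_a * rng.standard_normal(n)
        prop_b = b + scale * base_sd_b * rng.standard_normal(n)
        A_prop, S_prop = suffstats(prop_a, prop_b)
        dll = -0.5 * ((A_prop - A_cur) + (S_prop - S_cur) / phi)
        da_c, db_c = a - m[0], b - m[1]
        da_p, db_p = prop_a - m[0], prop_b - m[1]
        q_cur = (
            sigma_inv[0, 0] * da_c**2
            + 2 * sigma_inv[0, 1] * da_c * db_c
            + sigma_inv[1, 1] * db_c**2
        )
        q_prop = (
            sigma_inv[0, 0] * da_p**2
            + 2 * sigma_inv[0, 1] * da_p * db_p
            + sigma_inv[1, 1] * db_p**2
        )
        log_alpha = dll - 0.5 * (q_prop - q_cur)
        acc = np.log(rng.random(n)) < log_alpha
        a[acc], b[acc] = prop_a[acc], prop_b[acc]
        A_cur[acc], S_cur[acc] = A_prop[acc], S_prop[acc]
        window_accepts += acc
        if it >= spec.burn_in:
            accepts += acc

        # adapt proposal scales toward target acceptance during burn-in only
        if it < spec.burn_in and (it + 1) % spec.adapt_interval == 0:
            rate = window_accepts / spec.adapt_interval
            scale *= np.exp((rate - spec.target_acceptance))
            scale = np.clip(scale, 1e-2, 1e2)
            window_accepts[:] = 0.0

        # --- Gibbs update of m
        u_sum = np.array([a.sum(), b.sum()])
        prec = prior_prec_m + n * sigma_inv
        cov_m = _inv2(prec)
        mean_m = cov_m @ (prior_prec_m @ m0 + sigma_inv @ u_sum)
        m = mean_m + np.linalg.cholesky(cov_m) @ rng.standard_normal(2)

        # --- Gibbs update of Sigma^-1 ~ Wishart(nu + n, (R^-1 + S)^-1)
        da_c, db_c = a - m[0], b - m[1]
        S_mat = np.array(
            [
                [np.dot(da_c, da_c), np.dot(da_c, db_c)],
                [np.dot(da_c, db_c), np.dot(db_c, db_c)],
            ]
        )
        post_scale = _inv2(R_inv + S_mat)
        sigma_inv = _wishart_2x2(rng, spec.wishart_df + n, post_scale)
        sigma = _inv2(sigma_inv)

        # --- Gibbs update of phi (conditionally conjugate inverse-gamma)
        if not fixed_var:
            # S_cur holds sum r^2/w, which is phi-free
            shape = ig_a + 0.5 * N_total
            rate = ig_b + 0.5 * S_cur.sum()
            phi = rate / rng.gamma(shape)

        if it >= spec.burn_in:
            k = it - spec.burn_in
            draws_a[k] = a
            draws_b[k] = b
            draws_m[k] = m
            draws_sigma[k] = (sigma[0, 0], sigma[0, 1], sigma[1, 1])
            draws_phi[k] = phi

    p_gt_0 = (draws_b > spec.improved_threshold).mean(axis=0)
    p_lt_neg1 = (draws_b < spec.declining_threshold).mean(axis=0)
    classes = classify_slope(p_gt_0, p_lt_neg1, spec)
    return SlopeFit(
        patient_ids=ids,
        draws_intercept=draws_a,
        draws_slope=draws_b,
        draws_m=draws_m,
        draws_sigma=draws_sigma,
        draws_phi=draws_phi,
        p_gt_0=p_gt_0,
        p_lt_neg1=p_lt_neg1,
        classes=classes,
        acceptance_rate=accepts / n_kept,
        spec=spec,
    )
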