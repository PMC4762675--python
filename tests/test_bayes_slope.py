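"""Hierarchical Bayesian slope model: classification rule, conjugate-limit
equivalence, parameter recovery, shrinkage relative to OLS."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from egfr_traj import (
    SlopeModelSpec,
    classify_slope,
    fit_hierarchical_model,
    ols_slope,
)


def spec(**kw):
    return dataclasses.replace(SlopeModelSpec(), **kw)


def make_points(patients, seed=0):
    """patients: list of (id, intercept, slope, times, noise_sd)."""
    rng = np.random.default_rng(seed)
    rows = []
    for pid, a, b, times, sd in patients:
        for t in times:
            rows.append((pid, t, a + b * t + (rng.normal(0, sd) if sd else 0.0)))
    return pd.DataFrame(rows, columns=["patient_id", "time", "egfr"])


class TestClassificationRule:
    def test_forced_by_rule(self):
        assert classify_slope(1.0, 0.0) == "improved"
        assert classify_slope(0.5, 0.2) == "stable"
        assert classify_slope(0.0, 0.96) == "declining"

    def test_thresholds_are_strict(self):
        assert classify_slope(0.95, 0.0) == "stable"
        assert classify_slope(0.0, 0.95) == "stable"
        assert classify_slope(0.9501, 0.0) == "improved"

    def test_impossible_joint_classification_raises(self):
        with pytest.raises(RuntimeError):
            classify_slope(0.96, 0.96)


class TestOls:
    def test_two_point_slope(self):
        pts = make_points([("p", 50.0, 4.0, [0.0, 1.0], 0.0)])
        out = ols_slope(pts)
        assert out["ols_slope"].iloc[0] == pytest.approx(4.0)

    def test_flat_series(self):
        pts = make_points([("p", 50.0, 0.0, [0.0, 1.0, 2.0, 3.0], 0.0)])
        assert ols_slope(pts)["ols_slope"].iloc[0] == pytest.approx(0.0)

    def test_single_time_errors(self):
        pts = pd.DataFrame(
            {"patient_id": ["p", "p"], "time": [1.0, 1.0], "egfr": [50.0, 51.0]}
        )
        with pytest.raises(ValueError, match="p"):
            ols_slope(pts)


class TestHierarchicalFit:
    def test_noise_free_patient_recovered(self):
        """A patient lying exactly on 55 + 4t is classified improved with a
        posterior mean slope within 0.1 of 4."""
        rng = np.random.default_rng(8)
        others = [
            (f"q{i}", rng.uniform(48, 58), rng.normal(0, 1), np.linspace(0, 4, 6), 0.05)
            for i in range(15)
        ]
        pts = make_points(
            [("target", 55.0, 4.0, np.linspace(0, 4.5, 10), 0.0)] + others, seed=1
        )
        # vague dispersion prior so the (noise-free) likelihood dominates
        fit = fit_hierarchical_model(
            pts,
            spec(
                n_iterations=2000,
                burn_in=500,
                dispersion_prior=(1e-3, 1e-3),
                seed=2,
            ),
        )
        post = fit.posterior("target")
        assert post.posterior_mean_slope == pytest.approx(4.0, abs=0.1)
        assert post.p_gt_0 > 0.99
        assert post.slope_class == "improved"

    def test_non_finite_values_rejected(self):
        pts = pd.DataFrame(
            {"patient_id": ["p", "p"], "time": [0.0, 1.0], "egfr": [50.0, np.nan]}
        )
        with pytest.raises(ValueError):
            fit_hierarchical_model(pts)

    def test_single_point_patient_rejected(self):
        pts = pd.DataFrame({"patient_id": ["p"], "time": [0.0], "egfr": [50.0]})
        with pytest.raises(ValueError, match="p"):
            fit_hierarchical_model(pts)

    def test_chain_deterministic_given_seed(self):
        pts = make_points(
            [(f"p{i}", 52.0 + i, (-1) ** i, np.linspace(0, 3, 5), 2.0) for i in range(10)],
            seed=3,
        )
        s = spec(n_iterations=300, burn_in=100, seed=5)
        f1 = fit_hierarchical_model(pts, s)
        f2 = fit_hierarchical_model(pts, s)
        assert np.array_equal(f1.draws_slope, f2.draws_slope)
        assert np.array_equal(f1.draws_m, f2.draws_m)

    def test_population_recovery(self):
        """With 200 patients drawn from m=(53, -0.5), Sigma=diag(16, 4), the
        posterior mean of m lies within 3 posterior SDs of the truth."""
        rng = np.random.default_rng(11)
        m_true = np.array([53.0, -0.5])
        sd = np.array([4.0, 2.0])
        patients = []
        for i in range(200):
            a, b = m_true + sd * rng.standard_normal(2)
            times = np.sort(rng.uniform(0, 4.5, rng.integers(4, 10)))
            patients.append((f"p{i:03d}", a, b, times, np.sqrt(0.3 * max(a, 5))))
        pts = make_points(patients, seed=12)
        fit = fit_hierarchical_model(pts, spec(n_iterations=2500, burn_in=800, seed=13))
        for k in range(2):
            post_mean = fit.draws_m[:, k].mean()
            post_sd = fit.draws_m[:, k].std()
            assert abs(post_mean - m_true[k]) < 3 * post_sd, (k, post_mean, post_sd)
        # dispersion phi recovered in the right neighbourhood
        assert 0.15 < fit.draws_phi.mean() < 0.6

    def test_shrinkage_toward_population_mean(self, small_cohort):
        """Bayesian slopes sit closer to the population mean than OLS slopes
        on average (the model's variance-stabilising property)."""
        pts = small_cohort["points"]
        fit = fit_hierarchical_model(pts, spec(n_iterations=1500, burn_in=500, seed=21))
        ols = ols_slope(pts).set_index("patient_id")["ols_slope"]
        post = pd.Series(fit.posterior_mean_slope, index=fit.patient_ids)
        m_hat = fit.draws_m[:, 1].mean()
        assert (post - m_hat).abs().mean() < (ols - m_hat).abs().mean()

    def test_classification_consistency_in_measurement_count(self):
        """For a true slope of +3, the posterior probability of improvement
        is monotone non-decreasing in the number of measurements."""
        rng = np.random.default_rng(31)
        probs = []
        for n_points in (4, 16, 64):
            others = [
                (f"q{i}", rng.uniform(48, 58), rng.normal(0, 1.5),
                 np.linspace(0, 4, 8), 3.5)
                for i in range(25)
            ]
            pts = make_points(
                [("target", 53.0, 3.0, np.linspace(0, 4.5, n_points), 3.5)] + others,
                seed=n_points,
            )
            fit = fit_hierarchical_model(
                pts, spec(n_iterations=1500, burn_in=500, seed=n_points)
            )
            probs.append(fit.posterior("target").p_gt_0)
        assert probs[0] <= probs[1] <= probs[2]
        assert probs[2] > 0.99

    def test_classification_stable_under_burn_in_choice(self):
        pts = make_points(
            [("up", 52.0, 5.0, np.linspace(0, 4, 8), 1.0),
             ("down", 55.0, -5.0, np.linspace(0, 4, 8), 1.0)]
            + [(f"q{i}", 53.0, 0.0, np.linspace(0, 4, 8), 1.0) for i in range(8)],
            seed=41,
        )
        classes = []
        for burn in (500, 1500):
            fit = fit_hierarchical_model(
                pts, spec(n_iterations=2000, burn_in=burn, seed=42)
            )
            classes.append(dict(zip(fit.patient_ids, fit.classes)))
        assert classes[0] == classes[1]
        assert classes[0]["up"] == "improved"
        assert classes[0]["down"] == "declining"


def closed_form_posterior(times, y, sigma2, m0, S0):
    """Exact normal posterior of (a, b) for a known-variance linear model."""
    X = np.column_stack([np.ones_like(times), times])
    prec = np.linalg.inv(S0) + X.T @ X / sigma2
    cov = np.linalg.inv(prec)
    mean = cov @ (np.linalg.inv(S0) @ m0 + X.T @ y / sigma2)
    return mean, cov


class TestConjugateLimit:
    def test_matches_closed_form_posterior(self):
        """Homoscedastic known-variance limit: with the hyperpriors pinned,
        MCMC posterior means and SDs of (a, b) match the conjugate normal
        posterior within 3 Monte-Carlo standard errors (10 random datasets)."""
        import arviz as az

        rng = np.random.default_rng(55)
        m0 = np.array([52.0, 0.0])
        S0 = np.diag([25.0, 4.0])
        sigma2 = 16.0
        nu = 1e5
        failures = []
        for rep in range(10):
            n = int(rng.integers(4, 10))
            times = np.sort(rng.uniform(0, 5, n))
            a, b = m0 + np.sqrt(np.diag(S0)) * rng.standard_normal(2)
            y = a + b * times + rng.normal(0, np.sqrt(sigma2), n)
            pts = pd.DataFrame(
                {"patient_id": "p", "time": times, "egfr": y}
            )
            s = spec(
                n_iterations=4000,
                burn_in=1000,
                variance_mode="fixed",
                fixed_variance=sigma2,
                hyperprior_mean=tuple(m0),
                hyperprior_sd=(1e-4, 1e-4),  # pins m at m0
                wishart_df=nu,
                wishart_scale=tuple(map(tuple, np.linalg.inv(S0) / nu)),  # pins Sigma
                seed=100 + rep,
            )
            fit = fit_hierarchical_model(pts, s)
            mean, cov = closed_form_posterior(times, y, sigma2, m0, S0)
            for j, draws in enumerate(
                (fit.draws_intercept[:, 0], fit.draws_slope[:, 0])
            ):
                draws = draws.astype(float)
                ess = max(float(az.ess(draws)), 10.0)
                mc_se = draws.std() / np.sqrt(ess)
                if abs(draws.mean() - mean[j]) > 3 * mc_se:
                    failures.append((rep, j, draws.mean(), mean[j], mc_se))
                # posterior SD agrees within 15%
                assert np.isclose(
                    draws.std(), np.sqrt(cov[j, j]), rtol=0.15
                ), (rep, j)
        assert len(failures) <= 2, failures  # ~3 SE: rare misses tolerated
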