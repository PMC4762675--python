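# egfr-traj

Renal-function trajectory analysis for longitudinal eGFR data: who improves,
what happens to them afterwards, and how it relates to death.

Patients with early CKD stage 3 (eGFR 45–60 ml/min/1.73 m²) sometimes show
a *rising* eGFR slope — and, counterintuitively, carry an increased risk of
death. This package implements the full analysis pipeline for studying that
phenomenon on irregular laboratory time series:

1. **Derived variables** — CKD-EPI (2009) eGFR from serum creatinine,
   annualised % changes, albuminuria categories, annual averaging.
2. **Cohort assembly** — inclusion by an in-range initial eGFR with a
   confirmatory in-range value ≥ 90 days later, entry time T0 at the last
   pre-period eGFR, 5-year baseline covariate capture, exclusion logging,
   and sensitivity variants as configuration.
3. **Bayesian slope classification** — a hierarchical mixed-effects model
   `y_ij ~ N(a_i + b_i t_ij, φ·μ_ij)`, `(a_i, b_i) ~ BVN(m, Σ)` with
   normal/Wishart hyperpriors, fitted by Metropolis-within-Gibbs; a patient
   is *improved* if P(b_i > 0) > 0.95, *declining* if P(b_i < −1) > 0.95,
   otherwise *stable*. Posterior shrinkage corrects the positive-slope
   overestimation that per-patient OLS suffers under noise.
4. **Pattern-mixture trajectory model** — a K-group mixture of quadratic
   curves over post-entry annual-average eGFR with a measurement-count
   covariate and a death-year-measurement indicator for informative
   dropout, fitted by EM; K chosen by BIC improvement plus >70% average
   posterior assignment probability (APPA).
5. **Phenotypes** — trajectory groups collapse to HIPT / IIMNT / LIFNT /
   HIFNT from intercept level (cuts 60, 70) and annual % change (cuts 0,
   −3).
6. **Association models** — Cox proportional hazards for death at 1/3/5/9
   year horizons, multinomial logistic models of class and phenotype
   membership, and albuminuria-interaction Wald tests.

Because the registry data such analyses target are not redistributable, the
package includes a first-class synthetic cohort generator with the same
statistical structure (covariate-linked latent classes, heteroscedastic
noise, informative dropout tied to death, covariate-linked survival), and
the test suite validates every stage by recovering planted truth.

## Worked example

```python
import dataclasses
from egfr_traj import (
    GeneratorConfig, SlopeModelSpec,
    generate_cohort, build_cohort, fit_hierarchical_model,
)
from egfr_traj.cohort import pre_t0_points

cfg = dataclasses.replace(GeneratorConfig(), n_patients=1000, seed=7)
synth = generate_cohort(cfg)

cohort, exclusions = build_cohort(synth.measurements, synth.patients)
print(f"included {len(cohort)} of {cfg.n_patients} patients")
print(exclusions["reason"].value_counts().to_dict())

points = pre_t0_points(synth.measurements, synth.patients, cohort)
spec = dataclasses.replace(SlopeModelSpec(), n_iterations=2000, burn_in=500, seed=7)
fit = fit_hierarchical_model(points, spec)
print(fit.to_frame()["slope_class"].value_counts().to_dict())

post = fit.posterior(fit.patient_ids[0])
print(f"{post.patient_id}: slope {post.posterior_mean_slope:.2f}, "
      f"P(b>0)={post.p_gt_0:.3f}, class={post.slope_class}")
```

prints

```
included 802 of 1000 patients
{'initial eGFR out of range': 183, 'no second qualifying eGFR': 15}
{'stable': 557, 'declining': 130, 'improved': 115}
P000001: slope -0.06, P(b>0)=0.475, class=stable
```

802 of 1,000 simulated patients qualify (the rest mostly start outside the
45–60 window). The posterior classification is deliberately conservative:
55.7% are called stable although only 55% are stable by construction —
patients without 95% posterior certainty stay in the reference class.
The first patient's slope posterior is centred near zero with
P(b > 0) ≈ 0.48, so they are classified stable.

The same analysis end to end, from the shell:

```bash
egfr-traj run --seed 7 --n 1000 --out results/
```

writes `cohort.csv`, `exclusions.csv`, `slopes.csv`, `annual_egfr.csv`,
`trajectories.json` (coefficients, BIC/APPA ladder), `memberships.csv`,
`phenotypes.csv` and `report.json` (descriptives by class, hazard-ratio
grids by horizon, odds-ratio grid, phenotype map).

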