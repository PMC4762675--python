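# Methods

This note documents the statistical models implemented in `egfr_traj`, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not establish.

## Setting

The package analyses longitudinal kidney function in an early CKD stage 3
cohort (eGFR 45–60 ml/min/1.73 m²). Follow-up is split at a fixed cutover
date: eGFR measurements in a five-year pre-period determine each patient's
*slope class* (improved / stable / declining); patients with an improved
slope are then followed for up to nine further years and grouped by their
subsequent *renal-function trajectory*; trajectory groups are collapsed into
four clinical phenotypes; and mortality is modelled against slope class and
phenotype. Because the administrative data this design targets cannot be
redistributed, the package ships a synthetic-cohort generator with the same
statistical structure, and every stage is validated by recovery of planted
truth.

## Derived variables

eGFR is computed from serum creatinine with the 2009 four-variable CKD-EPI
equation (sex-specific knot κ = 0.7/0.9 mg/dL, exponents α = −0.329/−0.411
below the knot and −1.209 above, age factor 0.993^age, female factor 1.018,
black-race factor 1.159). The implementation is vectorised `min/max` form;
tests compare it against an independently coded piecewise reference on a
1,000-point grid at 1e-6. An exact inverse (creatinine from eGFR) exists
because the equation is strictly decreasing in creatinine; the generator
uses it in creatinine-emitting mode so the conversion path is exercised
end to end.

Annualised percentage eGFR change between the initial and entry (T0)
values is `[(T0 − initial)/initial] / [days/365.25] × 100` (%/yr); weight
change is the analogous first-to-last computation. Urine
albumin/creatinine (mg/g) is categorised `<20` normal, `20–300`
microalbuminuria (closed interval — the only reading under which the three
printed ranges partition the line), `>300` albuminuria. Annual averaging
uses half-open year bins `[T0 + k·365.25 d, T0 + (k+1)·365.25 d)`; years
with no measurements are absent rather than zero, and the bin counts become
the trajectory model's measurement-frequency covariate.

## Cohort assembly

A patient enters the cohort when their first eGFR inside the slope window
(default 1999-10-01 to 2004-09-30) lies in [45, 60] (inclusive endpoints)
and, under the primary configuration, a second in-range eGFR exists at
least 90 days later inside the window. T0 is the date of the last eGFR on
or before the window's end; survival runs from T0 to death or
administrative censoring at 2013-09-30. Baseline covariates come only from
the five years preceding T0. Same-day eGFR values are averaged (avoids
order dependence). The exclusion log records, per patient, the *first*
rule that removed them, and log plus cohort always account for every input
patient. Sensitivity variants — wider slope window, washout exclusions by
flag column, a minimum pre-T0 measurement count, ESRD (eGFR < 15)
exclusion or censoring — are configuration switches, not code paths of
their own. Comorbidity flags are consumed as given 0/1 columns; when a
dated flag-event table is supplied instead, events are filtered to the
baseline window (the package does not parse diagnosis codes).

## Bayesian slope model

For patient *i* with eGFR `y_ij` at time `t_ij` (years since that
patient's initial eGFR):

    y_ij ~ N(a_i + b_i t_ij,  φ·max(μ_ij, 5))
    (a_i, b_i) ~ BVN(m, Σ)
    m_k ~ N(m0_k, s0_k²),   Σ⁻¹ ~ Wishart(ν, R),   φ ~ InvGamma(a, b)

The residual variance is proportional to the mean eGFR — clipped below at
5 ml/min/1.73 m² so it stays positive — which captures the level-dependent
noise of creatinine-based eGFR. Because the mean enters the variance, the
random effects are not conjugate: they are updated by per-patient
random-walk Metropolis with scales adapted toward ~30% acceptance during
burn-in only (adaptation is frozen afterwards to preserve ergodicity). All
other updates are Gibbs: `m` (normal), `Σ⁻¹` (Wishart via Bartlett), and —
since `r²/w` sums are φ-free given the random effects — φ itself
(inverse-gamma), which is exact and cheaper than the Metropolis step a
fully non-conjugate treatment would need. The chain runs 1,000 burn-in
plus 5,000 kept iterations by default and is deterministic given the seed.

The hyperprior constants (m0 = (53, 0), s0 = (20, 5), ν = 3,
R = diag(100, 10), φ ~ InvGamma(2, 2)) are weakly informative on the CKD
stage 3 scale. The upstream study calibrated these from prior work it did
not print, so the defaults reproduce the model family rather than
unavailable numbers; every one is overridable. A config switch selects
whether the variance tracks the fitted mean `μ_ij` (default) or the
patient's average eGFR.

Classification uses kept draws only and strict inequalities: *improved*
iff P(b_i > 0) > 0.95, *declining* iff P(b_i < −1) > 0.95, otherwise
*stable*. The rule is deliberately conservative: per-patient OLS slopes
overstate the positive-slope fraction under noise, and the hierarchical
posterior shrinks toward the population mean. A consequence worth stating
plainly: with realistic visit densities (7–8 measurements over ~3.5 years)
and φ ≈ 0.3, the per-patient slope standard error is ≈1–1.5
ml/min/1.73 m²/yr, so true slopes of ±3 are classified with high
specificity (>0.98) but only ~0.5 sensitivity — most such patients simply
do not carry 95% posterior certainty. Sensitivity rises with visit count
and with slope magnitude (the generator's default ±4.0/−4.8 classes fare
better). Validation covers a homoscedastic known-variance limit in which
the posterior is available in closed form (the sampler matches it within
Monte-Carlo error), population-parameter recovery, and the
shrinkage-versus-OLS inequality.

## Pattern-mixture trajectory model

Post-entry annual-average eGFR of the improved subcohort is modelled as a
K-group finite mixture of quadratic curves in years since T0:

    y_it | group k ~ N(β_k0 + β_k1 t + β_k2 t² + γ·x_it + δ·d_i,  σ²)

with mixing proportions π, `x_it` the number of measurements in year *t*,
and `d_i` the indicator that the patient had an eGFR measurement in the
year of their death — the pattern-mixture covariate that conditions the
outcome model on the dominant missingness pattern. Missing years are
otherwise omitted from the likelihood. Fitting is EM: Bayes-rule
memberships across each patient's full year series in the E-step; a single
weighted least-squares solve for (β, δ, γ) plus closed-form π and σ² in
the M-step. The log-likelihood is asserted non-decreasing every iteration.
Restarts initialise from k-means on per-patient (mean, slope) summaries
with jitter; groups are reported intercept-descending so labels are
canonical, and the selected model is invariant to patient order.

δ is **shared across groups by default**. With a free per-group δ and a
generously chosen K, the mixture can manufacture a spurious group whose
large δ absorbs the dying members of a neighbouring level — confounding
group level with the missingness offset (observed in validation as a
"δ = +10" middle group collecting high-intercept decedents and distorting
downstream hazard ratios). The group-specific variant, and a variant in
which `d_i` instead enters the membership probabilities, remain config
switches.

The number of groups is accepted when BIC(K) < BIC(K−1) (BIC =
−2 logL + p log N, N patients) *and* every group's average posterior
probability of assignment (APPA) exceeds 0.70; the largest accepted K is
selected, the full (K, BIC, min-APPA) ladder is reported, and K = 1 with a
warning is returned when nothing qualifies. On synthetic panels with
patient-level heterogeneity BIC tends to over-segment (selecting 5–6
groups for 3 planted levels) — the same behaviour that yields many groups
on real cohorts — which is why the phenotype stage collapses groups rather
than interpreting K itself.

## Phenotypes

Each fitted group is placed on a grid of intercept level (low < 60 ≤
intermediate < 70 ≤ high, ml/min/1.73 m²) and average annual % eGFR change
(positive > 0 ≥ mild negative > −3 ≥ fast negative, %/yr), computed per
patient from first/last annual means and averaged within group. The four
named cells are HIPT (high, positive), IIMNT (intermediate, mild), LIFNT
(low, fast) and HIFNT (high, fast). The cut values are the round numbers
that separate the canonical seven-group solution into these phenotypes and
are configurable. Combinations outside the four named cells map to the
nearest rule by grid distance (ties prefer IIMNT, the modal reference
category) with an explicit warning.

## Mortality and membership models

Cox proportional-hazards models estimate the hazard of death at 1/3/5/9
year horizons, with follow-up administratively truncated at the horizon
(deaths beyond it are censored there); a landmark variant that instead
drops patients censored early is available by flag. Ties use Breslow by
default (Efron by flag); estimation is Newton maximisation of the partial
likelihood via statsmodels `PHReg`, which converges tightly enough to be
checked against a hand-written partial-likelihood maximiser at 1e-8. The
fully adjusted covariate set is age (linear), race (two indicators vs
white), sex, the ten comorbidity flags and T0 eGFR; weight change and
albuminuria enter complete-case only in the models that adjust for them. A
95% CI excluding 1 is reported as significant. Slope-class and phenotype
membership are modelled by maximum-likelihood multinomial logit
(statsmodels `MNLogit`), validated against binary logistic on a 2-level
reduction and against closed-form contingency-table odds ratios.
Exposure-by-albuminuria interactions are Wald tests on Cox product terms,
per term and jointly.

## Synthetic-data generator

The generator is the package's study-conditions module, not a fixture. Per
patient: demographics (96% male, 88/11/2% white/black/other, age ≈
N(71, 8²) truncated to 45–95) and ten comorbidity flags at the prevalences
of an elderly male CKD cohort; a latent slope class drawn from a
multinomial logit whose intercepts are numerically calibrated so the
marginal mix equals 20/55/25 despite covariate links (diabetes,
hypertension and chronic lung disease shift class odds with log-odds in
the 0.1–0.7 range); random effects (a_i, b_i) around class slope means
+4.0 / −0.4 / −4.8 ml/min/1.73 m²/yr with intercept ≈ N(53.5, 3.5²);
visits from a Poisson process at 2/yr starting uniformly in the first four
window years, preceded by a guideline-style confirmatory re-test 3–6
months after the first measurement (the 90-day inclusion rule presupposes
one; without it, class-dependent drift out of [45, 60] biases the included
class mix); measurement noise N(0, φ·max(μ, 5)) with φ = 0.3 and a 2
ml/min/1.73 m² lab floor; values rounded to 3 decimals (4 for
creatinine).

After the cutover, improved-class patients switch to one of three latent
trajectory groups — (intercept 80, +0.5/yr), (62, −1.5/yr), (50, −3.5/yr)
with shares 15/60/25% and patient-level intercept spread of 2 — while
other classes continue their line. Death is exponential from the cutover
with log-hazard in class (declining +0.30), latent group (+0.60/+0.10/
+0.35 — the highest planted on the HIPT-linked group, the ordering the
end-to-end check must recover), age (+0.06/yr) and diabetes (+0.30), on a
baseline of 0.053/yr. Informative missingness has two arms: measurements
after death are deleted, and a class-specific fraction of decedents
(15/35/25%) stops being measured up to two years before death. Patients
measured in their death year receive a −5 ml/min/1.73 m² offset on
post-cutover means — the signal the pattern-mixture δ recovers.

What the generator does *not* emulate: assay drift, within-day replicates,
care-seeking bursts around hospitalisations, covariate-dependent visit
rates, competing risks, or post-entry evolution of comorbidities. Passing
recovery tests therefore demonstrates internal correctness of the
estimators under the stated model, not robustness to these real-data
features. One deliberate realism *is* retained: measurement cessation
before death makes some missingness invisible to the death-year indicator,
so fitted fast-declining groups are mildly enriched with decedents and
their hazard ratios run above the planted values (observed ≈1.7 vs planted
1.42 for the LIFNT-linked group at the default scale).

## Numerical choices and problem sizes

Dates use a 365.25-day year throughout. The eGFR variance floor is 5
ml/min/1.73 m² in both generator and model. EM stops at a log-likelihood
gain below 1e-6 (500 iterations cap) with the best of 10 restarts (5 in
the end-to-end pipeline, candidate K capped at 6 there); mixture weights
are floored at 1e-12; the WLS normal equations carry a 1e-10 ridge.
MCMC proposals adapt every 50 burn-in iterations by
`scale ← scale·exp(rate − 0.3)`, clipped to [1e-2, 1e2]; slope draws are
stored in float32. The default validation scale is 4,000 generated
patients (≈3,300 included, ≈500 classified improved), which keeps the full
pipeline around a quarter of a minute on one CPU while leaving Monte-Carlo
error well inside the 3-SE bands the tests use; recovery experiments use
300–2,000 patients per the property being tested.

## Known limitations

- The slope-classification rule's sensitivity at moderate true slopes is
  intrinsically limited at realistic visit densities (see above); the
  package reports posterior probabilities so users can apply other cuts.
- BIC-based group-count selection over-segments under within-group
  heterogeneity; interpret phenotypes, not K.
- The Cox stage assumes proportional hazards and ignores competing risks;
  horizon effects are obtained by truncation, not by refitting landmark
  cohorts (the flag exists but is not the default).
- Multinomial and Cox models are complete-case in weight and albuminuria,
  mirroring the reduced n of the adjusted models they correspond to.
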