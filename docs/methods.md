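# Methods

This document describes the statistical methods implemented in `adhertraj`,
the choices made in the numerical implementation, and the design of the
synthetic-cohort generator used for validation.

## 1. Problem setting

Patients prescribed long-term oral therapy (the motivating case is adjuvant
endocrine therapy after breast cancer) appear in registry-style data as a
sequence of *registration visits*: dated events at which a fixed supply of
medication is recorded. The package answers three questions:

1. How adherent was each patient over time? (supply diaries → interval PDC)
2. Are there latent subgroups with distinct adherence trajectories?
   (censored-normal group-based trajectory model)
3. Which baseline characteristics predict membership in the declining
   groups? (multinomial logistic association models)

## 2. Supply diaries and PDC

Each registration adds a fixed supply (default 182 days, one dispensing
interval) to a per-patient balance that is consumed one day per day of
follow-up. At each interval boundary the balance carried into the next
interval is capped (default 182 days) *before* any same-day registration is
credited, so stockpiling cannot cover more than one future interval.

Follow-up runs from the initiation date (first registration) to the
earliest of: five years after diagnosis (1,826 days) or a censoring event
(recurrence, death, second primary, emigration). The proportion of days
covered (PDC) in interval *t* is covered days divided by interval length;
the final interval's denominator is shortened to the censoring date, and a
trailing fragment shorter than 14 days is dropped.

The engine is event-driven (registrations, interval boundaries, end of
follow-up) rather than a per-day loop; tests verify it against an
independent per-day brute-force oracle on randomized fixtures.

### Eligibility cascade

Applied in a fixed order, each patient counted at most once, at the first
step that removes them:

1. ER-negative disease (only if the input has an `er_status` column);
2. no AET registration at all;
3. under one year between initiation and end of follow-up;
4. age ≥ 55 at diagnosis, or initiation on an aromatase inhibitor
   (the target population is premenopausal tamoxifen initiators);
5. implausible initiation timing: initiation before diagnosis, or after a
   recurrence/second-primary event.

A patient whose initiation date falls *after* their censoring date is
deliberately not counted at step 3 (where end − initiation is negative)
but at step 5, which is the step describing the actual defect.

## 3. Censored-normal group-based trajectory model

PDC is a fraction in [0, 1] with mass at both endpoints (perfect adherers
at 1, discontinuers at 0). We model the panel with a latent-class Tobit
model: patient *i* belongs to group *j* with probability π_j; within group
*j* the latent adherence at scaled time *s* is

  y*_{it} = β_j' (1, s, s², …) + ε_{it},  ε ~ N(0, σ²),  shared σ,

and the observed PDC is y = min(1, max(0, y*)). Time is scaled as
s = t / T_max so polynomial coefficients are well-conditioned. The
per-observation likelihood is Φ((0−μ)/σ) at y = 0, 1 − Φ((1−μ)/σ) at
y = 1, and φ((y−μ)/σ)/σ in the interior.

### Estimation

EM with posteriors over group membership, where the M-step maximizes the
expected complete-data log-likelihood by L-BFGS with analytic gradients
(a generalized EM step: the inner optimizer is capped at 15 iterations,
which preserves the monotone-ascent property while avoiding long crawls
on nearly flat ridges). After at most 30 EM iterations, or earlier on
relative-change convergence, the fit is *polished* by direct L-BFGS on the
full parameter vector (all β, J−1 mixing logits, log σ), using the
identity that the observed-data score equals the posterior-weighted
complete-data score. The polish runs up to four rounds of 400 iterations
and stops on optimizer success or when a round improves the
log-likelihood by less than the relative tolerance. This two-phase scheme
exists because plain EM converges very slowly for overspecified J (extra
groups sit on a non-identified ridge); the direct phase traverses the
ridge quickly, which matters during model selection where J is scanned
past its true value.

Each fit uses multiple restarts: the first initializes from quantile
splits of patient-mean PDC with per-stratum least squares; later restarts
perturb the coefficients and reshuffle 10% of the initial assignment.
Groups are relabeled after fitting so group 1 always has the highest mean
fitted trajectory.

Standard errors come from the observed information matrix, computed by
central-difference numerical differentiation of the full log-likelihood
in (β, mixing logits, log σ); predicted trajectories report delta-method
CIs for the censored mean E[y] = 1 − Φ(b) + μ(Φ(b) − Φ(a)) + σ(φ(a) − φ(b))
with a = (0−μ)/σ, b = (1−μ)/σ.

### Model selection (three steps)

1. **Number of groups.** Fit J = 2…7, all groups quadratic; choose by BIC
   (log L − ½ k ln n, larger better; k counts polynomial coefficients,
   J − 1 mixing probabilities, and σ) among converged fits whose smallest
   group holds ≥ 2% of patients.
2. **Polynomial orders.** Iteratively remove the highest-order term with
   the least significant Wald statistic (α = 0.05), refitting after each
   removal, until every group's leading term is significant or constant.
3. **Diagnostics.** Average posterior probability of assignment (APPA,
   flag < 0.70), odds of correct classification (OCC), and assigned versus
   estimated group shares.

## 4. Association models

Group membership (modal posterior assignment) is the outcome of a
multinomial logistic regression (statsmodels `MNLogit`) with one model per
exposure; each model adjusts for a per-exposure adjustment set (chosen on
subject-matter grounds and encoded in `default_specs()`). The highest
adherence group is the outcome reference; the largest exposure level is
the default exposure reference. ORs use Wald 95% CIs. Exposure levels
with an empty exposure-by-outcome cell are dropped with a warning. With
an empty adjustment set the model reproduces the contingency-table
cross-product ORs exactly (tested to 1e-6 relative).

### Missing data

The three covariates designated as missable (`stage`, `tumor_size`,
`positive_nodes`) are completed by chained multinomial-logistic
imputation: each imputation initializes missing entries by draws from the
observed marginal, then runs 10 Gibbs cycles where each missable field is
modeled on all other covariates (fit on observed rows, drawn for missing
rows). The m = 50 completed datasets are aggregated by
mean-of-ordinal-codes-then-round, giving a single completed dataset for
the association stage. Note this is single-dataset completion for point
estimation; between-imputation variance is not propagated into the CIs.
Missingness outside the designated fields raises an error rather than
being silently imputed.

## 5. Synthetic-cohort generator

The generator produces registry-style tables (`patients`, `visits`,
`censoring`) with known ground truth:

- **Groups.** Patients are assigned to 3 latent groups; the default mixing
  is (0.57, 0.36, 0.07) with mean-adherence polynomials (on scaled time)
  of 0.96 (constant high), 0.95 − 0.25s − 0.22s² (slow decline), and
  0.85 − 1.85s + 0.90s² (rapid decline), residual σ = 0.15.
- **Covariate effects.** Baseline covariates shift group membership
  through a multinomial-logit model: softmax of group log-mixing plus
  per-covariate log-odds terms keyed `"covariate=level"`. The defaults
  configure known log-ORs (e.g. stage I: log 1.4 / log 1.9 on the slow /
  rapid groups vs. the high group) so association models can be validated
  against ground truth.
- **Visits.** Attendance at each 182-day registration window is Bernoulli
  with probability equal to the group's (noisy) latent adherence, so
  observed PDC panels reflect the group trajectories after passing through
  the actual diary engine. Refills after the first run late by a uniform
  delay of up to `refill_jitter_days` (default 45), opening coverage gaps
  that produce fractional interval PDC as in real dispensing data — with
  zero jitter, interval coverage is binary and the censored-normal model
  is unidentified (only μ/σ is estimable, as in a probit). Initiation is
  delayed lognormally (median 6.3 months); censoring events are
  exponential with per-cause hazards.
- **Missingness.** MCAR at 1% per missable field by default.

For trajectory-recovery tests, `simulate_panels` bypasses the visit layer
and draws censored-normal panels directly from the model, so recovery is
tested against the exact generating process.

**Scope/limits.** The generator emulates marginal covariate distributions
and effect sizes typical of a population-based breast-cancer registry; it
does not model covariate–covariate dependence (covariates are drawn
independently), informative censoring, or switching-related adherence
changes beyond a simple AI-switch flag.

An honest consequence of the visit-level design: observed interval PDC is
attendance-driven (a mixture of near-0/near-1 masses with jitter-induced
interior values), *not* censored-normal, so BIC applied to visit-level
simulated cohorts tends to select more groups than the three generating
latent classes — component overextraction under distributional
misspecification, a known behaviour of group-based trajectory models. The
parameter-recovery guarantees in the test suite are therefore defined on
`simulate_panels`, which draws panels from the censored-normal model
itself; there BIC selects three groups and recovers π, the curves and σ.

## 6. Numerical and reproducibility choices

- Dates are integer day offsets from an arbitrary origin; one month is
  30.4375 days; follow-up is 1,826 days; the dispensing interval is 182
  days.
- All stochastic stages fan out one user seed via
  `numpy.random.SeedSequence([seed, stage_index])`, so stage seeds are
  independent but fully determined by the run seed. Reruns are
  byte-identical (tested on the OR table and PDC panel).
- Log-likelihood tail terms use `exp(logpdf − logcdf)` ratios to stay
  finite far into the tails; σ is floored at 0.02 during initialization.
- A panel with no PDC variation (e.g. everyone perfectly adherent) cannot
  identify a mixture; the pipeline warns and falls back to a single-group
  model.

### Problem sizes

Full-scale defaults (n = 2,000 patients, J scanned 2–7, 5 restarts,
m = 50 imputations) complete in a few minutes. The test suite and the
acceptance script use reduced scans (fewer restarts, narrower J ranges,
fewer imputations) chosen for runtime, not for outcome; the
parameter-recovery checks still run at the full n = 2,000 scale.

## 7. Limitations

- Shared σ across groups (heteroscedastic extensions are not implemented).
- Modal posterior assignment ignores classification uncertainty in the
  association stage (no 3-step bias correction or pseudo-class draws).
- Imputation aggregates to a single completed dataset (see §4).
- The Wald pruning in selection step 2 tests one term at a time; joint
  tests of several high-order terms are not implemented.
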