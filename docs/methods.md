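# Methods

## The model

MHD (the monohydroxy derivative, oxcarbazepine's active metabolite) is
described by a one-compartment model with first-order absorption and
first-order elimination:

    dA_gut/dt  = -ka * A_gut
    dA_cent/dt =  ka * A_gut - ke * A_cent,        C(t) = A_cent / (V/F)

with ke = (CL/F)/(V/F).  Apparent clearance and volume carry allometric
body-weight covariates centred at 66 kg and log-normal interindividual
random effects (IIV):

    CL/F_i = theta1 * (WT_i/66)^theta2 * exp(eta_CL,i),   eta_CL ~ N(0, omega2_CL)
    V/F_i  = theta3 * (WT_i/66)^theta4 * exp(eta_V,i),    eta_V  ~ N(0, omega2_V)

Omega is diagonal (no IIV on ka, no CL-V covariance).  Observations carry
proportional residual error, y = f * (1 + sigma*eps), eps ~ N(0,1); additive
and combined error models are available through `FitConfig.error_model` but
proportional is the shipped default.  Registry observations are treated as
steady state on a fixed repeated schedule; the steady-state concentration is
the superposition closed form

    C_ss(t) = D*ka/(V(ka-ke)) * [ e^{-ke t}/(1-e^{-ke tau}) - e^{-ka t}/(1-e^{-ka tau}) ],

with the single-dose (Bateman) solution as its tau -> infinity limit.

Assumptions worth stating: linear (dose-proportional) kinetics, no lag time,
no parent-drug compartment, complete adherence to the recorded regimen, and
steady state for every registry sample.

### Numerical form of the concentration curve

The Bateman equation has a removable singularity at ka = ke and loses up to
seven digits to cancellation in (e^{-ke t} - e^{-ka t}) when ka is within
~1e-8 of ke.  Instead of branching to a limit form near the singularity, the
implementation evaluates the difference quotient

    R(s) = (e^{-ke s} - e^{-ka s}) / (ka - ke)
         = e^{-min(ka,ke) s} * (-expm1(-|ka-ke| s)) / |ka-ke|

through `expm1`, which is stable arbitrarily close to the singularity; the
analytic limit s*e^{-ke s} is used only at exact equality.  Single-dose and
steady-state curves share one expression, C = D*ka*(e^{-ke t} R(tau) +
P R(t)) / (V P Q) with P, Q the accumulation denominators (P = Q = 1 for a
single dose).  Continuity into the limit is tested at +-1e-12 relative.

## FOCE-I estimation

The marginal likelihood of the mixed model has no closed form.  First-order
conditional estimation with interaction (FOCE-I) linearizes the model in eta
around each subject's empirical Bayes mode.  Subject i's mode minimizes

    L_i(eta) = sum_j [ (y_ij - f_ij(eta))^2 / v_ij + log v_ij ] + eta' Omega^{-1} eta,

with v_ij = sigma_add^2 + sigma_prop^2 * f_ij(eta)^2 evaluated at the
conditional prediction (the "interaction").  Predictions are floored at
1e-10 mg/L inside the variance so v stays positive.  Note a small but real
consequence of the interaction term: a subject whose observations equal the
typical predictions exactly has a mode slightly off zero, because log v(f)
rewards marginally lower predictions.

The objective function value, in the NONMEM convention without the
n*log(2*pi) constant, is

    OFV = sum_i [ log|V_i| + r_i' V_i^{-1} r_i ],
    r_i = y_i - f_i(eta_hat_i) + G_i eta_hat_i,
    V_i = G_i Omega G_i' + diag(v_i),

where G_i = df_i/deta at the mode is obtained by central differences (step
1e-4).  Cross-subject summation uses `math.fsum`, making the OFV exactly
invariant to subject order.

### Inner problem

All subjects' modes are found simultaneously by a damped Gauss-Newton
iteration vectorized across the cohort: per-observation gradients are
accumulated with `bincount`, the 2x2 (or pinned 1x1) systems are solved in
closed form, and a per-subject backtracking line search guarantees descent.
Dimensions with omega2 = 0 are pinned at eta = 0 (the infinite-shrinkage
limit).  Convergence is a gradient norm below `inner_tol` (default 1e-6);
subjects for which no descent direction remains are frozen at their mode.
Modes are warm-started between outer iterations.

### Outer problem

The outer search runs unconstrained on transformed parameters: log for the
strictly positive ones (theta1, theta3, ka, omega2s, sigmas), log1p for
fractional covariate coefficients (so the CL multiplier 1 + beta stays
positive), identity for allometric exponents.  The optimizer is BFGS with an
explicit central-difference gradient (step 1e-6 on the transformed scale);
before each probe the eta warm start is reset to a common snapshot so the
inner search's hysteresis cancels from the differences.  Because a noisy
objective can end BFGS with a "precision loss" stop short of the optimum,
the driver restarts BFGS (fresh Hessian) until the between-round OFV gain
falls below `outer_tol` (default 1e-6 relative) — the convergence
definition — up to five rounds.  Multi-start (default 3, jittered by
N(0, 0.1^2) on the transformed scale, seeded) guards against outer local
minima.  OFV excursions during line searches can overflow by tens of orders
of magnitude; values above running-best + 1e3 are squashed through a
monotone log10 cap that leaves the landscape near the optimum untouched.

Earlier iterations of this code used bounded quasi-Newton and interior-point
trust-region drivers; both stalled systematically on the curved CL/V/ka
valley of this objective or on covariate coefficients started at zero, which
is why the fit uses its own gradient and restart logic.

### Standard errors

SEs come from the inverse of the central-difference Hessian of OFV/2 at the
optimum on the natural parameter scale.  The relative step is 5e-3: smaller
steps drown the curvature in the residual noise left by the iterative inner
search and can make the Hessian indefinite.  RSE% = 100*SE/|estimate|.  IIV
is reported as %CV ~= 100*omega, the common pharmacometric reporting
convention at these magnitudes.

## Stepwise covariate search

Body weight on CL/F and V/F is structural and never searched.  Candidates
(age as a power term, sex/ASM/EIASM flags as fractional terms on CL/F) enter
by forward selection — the largest OFV drop, if at least chi2_1(0.95) = 3.84 —
and must survive backward elimination — removal must raise the OFV by at
least chi2_1(0.99) = 6.63.  Both thresholds are computed from scipy's chi2
quantiles, not hard-coded.  Search fits start from the incumbent estimates
with a single start.

## Model evaluation

* **Bootstrap**: subjects are the resampling unit (all rows and covariates
  travel together); each replicate is refit starting from the original
  estimates with one start.  Medians and 2.5/97.5 percentiles are taken over
  converged replicates; >20% non-convergence is recorded as a warning.  The
  default is 1000 resamples; the test suite uses single-digit resample
  counts on reduced cohorts, which exercises the machinery but not the
  percentile accuracy.
* **VPC**: replicate datasets are simulated at the original design (same
  subjects, doses, times, weights; fresh eta and eps), stratified into the
  registry arm (bins at deciles of observed time after dose) and the
  single-dose arm (one bin per nominal sampling time, nearest-neighbour
  assignment of jittered times).  Bands are the 2.5/97.5 percentiles across
  replicates of each simulated percentile; empty bins are dropped with a
  warning.  No prediction correction is applied.
* **CWRES**: V_i^{-1/2} (y_i - (f_i(eta_hat) - G_i eta_hat)) with the
  symmetric eigendecomposition square root (CWRES is convention-dependent;
  this is the documented choice).  On well-specified simulated data the
  residuals are checked for mean ~ 0 and SD ~ 1.

## Exposure and adverse-event analysis

Individual CL/F uses the empirical Bayes eta; AUC = daily dose / CL/F_i
(the steady-state 24-h AUC — consistent with a mean AUC of ~650 mg*h/L at a
~999 mg mean daily dose), and the trough is the model concentration a full
interval after a dose under the subject's own regimen.  Group comparisons
use the two-sided Mann-Whitney U (normal approximation, tie and continuity
corrected — exact enumeration is unnecessary at these sample sizes) and the
two-sided Fisher exact test with the point-probability rule (the convention
that reproduces the published p = 0.614 case, which discriminates between
two-sided definitions).  ROC analysis calls a subject positive when exposure
exceeds the threshold; candidate thresholds are midpoints between
consecutive distinct values plus +-infinity, the cut-off maximizes Youden's
J = sensitivity + specificity - 1 with ties broken toward the lower
threshold, and the ROC area is the trapezoidal integral.  The adjusted
analysis is a maximum-likelihood logistic regression of the event on the
exposure metric plus sex, age and GFR, with Wald 95% CIs from the observed
information; separation and constant covariates are flagged, never silently
dropped into output.

## The synthetic cohort generator

The generator emulates the study design so the whole pipeline is testable
without any data download:

* 447 sparse registry subjects: weight ~ truncN(65.8, 12.5^2, [39, 116]) kg,
  age ~ truncN(39.2, 14.7^2, [16, 80]) y, 59.1% male, GFR ~ truncN(100,
  15^2, >=30) mL/min, daily dose ~ truncN(999, 338^2) rounded to 150-mg
  steps and clipped to [150, 2100], twice daily with probability 438/447
  (remainder split once/thrice daily), one steady-state sample at
  U(0, tau) after a dose, 5.1% EIASM co-medication plus individual ASM flags
  at roughly the reported prevalences (covariate-search fodder only).
* 40 rich single-dose subjects: 30 mg/kg, nominal times 2, 4, 6, 8, 12, 14,
  16, 24 h with +-10% uniform jitter and 5% of samples dropped (at least
  one kept), reproducing ~748 observations over 487 subjects.
* Truth parameters default to the reported adult estimates (CL/F 1.65 L/h,
  exponents 0.67/0.96, V/F 59 L, ka 0.34/h, IIV 29.2/41.5 %CV, sigma 0.13).
* DRAE labels (dose-related adverse events: dizziness, somnolence, headache,
  diplopia; hyponatremia excluded) are Bernoulli(expit(a + b*trough)) on the
  subject's model-true steady-state trough, with b = log(1.079) per mg/L
  (the reported trough odds-ratio scale) and a solved by root finding so the
  expected prevalence over the cohort's troughs is 6.26%.  "Sole dizziness"
  is a sub-flag with conditional probability 18/28.  Labels exist for the
  sparse arm only.
* Randomness: one master seed; subject i draws from
  `SeedSequence(seed, spawn_key=(i,))`, so enlarging a cohort never perturbs
  existing subjects.

What the generator does *not* emulate: non-adherence, recorded-time errors,
the enrolment funnel of excluded/unanalyzable samples, parent-drug (OXC)
kinetics, hyponatremia and sodium dynamics, seizure counts, dropout, or any
correlation between dose and body weight in the registry arm (the reported
dose-per-weight spread indicates no strict per-kg dosing there).  Passing
recovery tests on these cohorts therefore demonstrates correctness of the
estimator under the model's own assumptions, not robustness to real-world
violations of them.

A note on units: reported MHD levels of ~15,756 "mg/L" alongside troughs of
~12.75 mg/L are only consistent if the former is ug/L; the package
standardizes on mg/L throughout.  Model-implied troughs at the default truth
are ~20-25 mg/L, somewhat above the reported mean trough (12.75 mg/L) — the
source's troughs came from an unspecified simulation method, so the AE-link
intercept is calibrated to prevalence rather than to the trough scale.
EIASM membership (with or without valproate) is decided wherever the EIASM
flag column is produced, so either convention can be expressed in the data.

## Problem sizes

Default analyses: 487 subjects, 1000 bootstrap resamples, 1000 VPC
replicates.  The test suite and the acceptance script run the full-design
cohort fit with a single start from neutral initial values, and scale the
bootstrap (single-digit resamples on ~30-subject cohorts), covariate-search
simulations (120-400 sparse subjects with the V/ka side fixed, since sparse
steady-state data carry no absorption signal), and the quadrature
comparison (5-subject rich sets) to desk size; these sizes are stated in
each test.

## Known limitations

* FOCE-I is a linearization; its OFV is compared against adaptive
  Gauss-Hermite quadrature on rich toy sets (within 0.5), but agreement
  degrades for very sparse subjects with large IIV, as for any FOCE
  implementation.
* The one-sample-per-subject registry design identifies omega2_V only
  weakly; its estimate leans on the 40 rich subjects (visible in its RSE).
* Wald CIs for the logistic odds ratios and the percentile bootstrap are
  first-order methods; no profile likelihood or BCa correction is provided.
* The OFV trace recorded during fitting is monotone over accepted
  iterations up to tiny (<0.01) wiggles from finite-difference noise.
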