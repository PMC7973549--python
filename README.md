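# oxcpk

Population pharmacokinetics of oxcarbazepine's active metabolite (MHD) in
adults with epilepsy, and the downstream exposure–adverse-event analysis.

Oxcarbazepine (OXC) is almost completely converted to its monohydroxy
derivative (MHD), which carries the antiseizure effect; dose-related adverse
events (DRAEs — dizziness, somnolence, headache, diplopia) track MHD
exposure.  Real registry cohorts of this kind combine hundreds of sparsely
sampled patients (one steady-state sample each) with a small intensively
sampled single-dose study — a design that defeats per-subject curve fitting
and calls for nonlinear mixed-effects modelling.  This package implements
that full pipeline for pharmacometricians and clinical pharmacologists:

* a one-compartment, first-order-absorption PK model with allometric
  body-weight covariates and log-normal interindividual variability,

      CL/F = θ₁·(WT/66)^θ₂·e^η₁,   V/F = θ₃·(WT/66)^θ₄·e^η₂,
      C(t) = D·ka/(V(ka−ke))·(e^{−ke·t} − e^{−ka·t}),  ke = CL/V,

  with the steady-state superposition closed form for repeated dosing;
* FOCE-I (first-order conditional estimation with interaction) maximum
  likelihood for the population parameters θ, Ω = diag(ω²_CL, ω²_V) and the
  proportional residual error σ, with stepwise covariate search at the
  χ²(1) thresholds 3.84 (forward, p<0.05) and 6.63 (backward, p<0.01);
* model evaluation: nonparametric bootstrap (subject resampling), visual
  predictive checks stratified by study arm, and conditional weighted
  residuals (CWRES);
* exposure metrics (AUC = daily dose/(CL/F)ᵢ, steady-state trough) and their
  association with adverse events: Mann–Whitney/Fisher group tests, ROC
  curves with Youden-index cut-offs, and logistic regression adjusted for
  age, sex and GFR;
* a synthetic cohort generator that reproduces the study design (447 sparse
  + 40 rich subjects, demographics, dosing, sampling and an exposure-linked
  adverse-event process), so every stage is testable without any data
  access.

The registry data behind the original analysis are not public; the package
is validated by parameter-recovery simulation at the published estimates and
by independent oracles (ODE integration, adaptive Gauss–Hermite quadrature,
brute-force ROC search, direct likelihood maximization).  See
`docs/methods.md` for the model, algorithms and numerical choices.

## Worked example

Generate the default cohort, fit it, and derive exposures — as a library:

```python
from oxcpk import (CohortConfig, FitConfig, PopulationParameters,
                   derive_exposure, fit, generate)

cohort = generate(CohortConfig(seed=1))       # 487 subjects, 750 observations
start = PopulationParameters(theta1_cl=2.0, theta2_wt_cl=0.75, theta3_v=50.0,
                             theta4_wt_v=1.0, ka=0.5, omega2_cl=0.1,
                             omega2_v=0.1, sigma_prop=0.2)
res = fit(cohort.dataset, FitConfig(init=start, n_starts=1, seed=1))
e = res.estimates
print(f"CL/F {e.theta1_cl:.4f} L/h   V/F {e.theta3_v:.3f} L   ka {e.ka:.4f} /h")
```

prints

```
CL/F 1.6843 L/h   V/F 60.504 L   ka 0.3559 /h
```

— the fit recovers the generating values (typical CL/F 1.65 L/h, V/F 59 L,
ka 0.34 h⁻¹) from neutral starting values: apparent clearance within ~2%,
volume within ~3%, absorption rate within ~5%, with the body-weight exponent
on clearance at 0.70, interindividual variability of CL/F at 28.7 %CV and a
proportional residual SD of 0.134.  The same pipeline is available from the
shell:

```sh
oxcpk simulate --seed 1 -o cohort.csv --labels-out labels.csv
oxcpk fit cohort.csv --seed 1 -o fit.json --report fit.txt
oxcpk exposure cohort.csv fit.json -o exposure.csv
oxcpk ae exposure.csv labels.csv cohort.csv --metric trough --outcome drae
```

with further subcommands `covsearch`, `bootstrap`, `vpc` and `report`; all
accept a shared YAML config (`--config`) with `truth:`, `design:`, `fit:`
and `ae:` sections.

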