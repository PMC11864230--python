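# Methods note

This note records the statistical model, its assumptions, the numerical
choices, and the design decisions behind `proteoscreen`.

## 1. Exposure construction

### 1.1 Life's Essential 8 scoring

Each of the eight components maps raw inputs to 0–100 points via the
published American Heart Association gradations, stored as data
(`data/le8_defaults.yaml`) rather than code so the breakpoints are
inspectable and swappable:

- **Diet** — decile of adherence mapped linearly (top decile = 100).
- **Physical activity** — weekly moderate-to-vigorous minutes, thresholded
  (≥150 → 100 down to 0 → 0).
- **Nicotine** — five-level status (never → current) mapped to
  100/75/50/25/0, with a 20-point deduction for secondhand exposure
  (floored at 0).
- **Sleep** — hours per night, interval-scored with the 7–9 h optimum.
- **BMI** — interval-scored, <25 kg/m² = 100.
- **Lipids** — non-HDL cholesterol intervals, 20-point deduction if on
  lipid-lowering medication.
- **Glucose** — separate non-diabetic and diabetic band tables; the
  diabetic bands are expressed as estimated-average-glucose equivalents of
  the published HbA1c bands, so one input column serves both paths (a
  deliberate simplification recorded here).
- **Blood pressure** — category is the worse of the systolic and diastolic
  cut assignments; 20-point deduction if medicated.

Scores propagate NaN inputs and validate physiologic plausibility bounds.
The total (0–800) partitions exactly into lifestyle (diet, activity,
nicotine, sleep) and biological (BMI, lipids, glucose, blood pressure)
sub-scores of 0–400 each. The maximum of 800 for an all-optimal subject and
minimum of 0 for an all-worst subject are acceptance-tested through the
real scoring path.

### 1.2 Reverse-z exposure

The analysis exposure is `le8_z_rev = −(le8_total − mean)/sd` with the
sample mean and SD (ddof = 1), so +1 unit is one SD of *poorer*
cardiovascular health and "total effects" of poor health on outcomes carry
their natural sign. `reverse_z` refuses constant or near-degenerate inputs.
The socioeconomic covariate is a re-standardized composite
`z(z(income) + z(education) − z(deprivation))`.

## 2. Linear screening machinery

`fit_adjusted_ols` is ordinary least squares with an explicit intercept,
listwise deletion, classical covariance by default (HC1 optional), and a
pivoted-QR rank check that names the collinear columns instead of silently
dropping them. t-distributed p-values use the residual degrees of freedom.
Agreement with `statsmodels` to 1e-10 is part of the test suite;
`statsmodels` remains the independent cross-check rather than the engine so
the screen can be vectorized.

`mediator_screen` fits all proteins against a shared design in one pass:
the design pseudo-inverse is computed once and applied to the full protein
matrix, making the m ≈ 1,500-protein screen a single matrix product.
Per-protein residual variances give exact per-fit classical SEs, identical
to fitting each model separately (tested against `statsmodels` per
protein). Inputs whose SD falls outside [0.8, 1.2] are re-standardized with
a warning so effects stay on the SD-per-SD scale. Selection is
`p_bonferroni < 0.05 AND |effect| > 0.20`, both strict inequalities;
`p_bonferroni = min(1, m·p)` with the family size recorded on the output.

`heterogeneity_test` adds modifier × exposure product terms (dummy-coding
modifiers with >2 levels) and reports a joint Wald chi-square on the
interaction block. Null calibration (KS-uniform p-values over repeated
seeds) and power on planted slope differences are both tested.

## 3. Four-way effect decomposition

### 3.1 Point estimates

With the linear outcome model E[Y|a,m,c] = θ0 + θ1·a + θ2·m + θ3·a·m + θ4'c
and mediator model E[M|a,c] = β0 + β1·a + β2'c, the four components for the
contrast d = a − a\* and mediator reference m\* are closed-form:

```
CDE    = (θ1 + θ3·m*) · d
INTREF = θ3 · (β0 + β1·a* + β2'c̄ − m*) · d
INTMED = θ3 · β1 · d²
PIE    = (θ2 + θ3·a*) · β1 · d
TE     = CDE + INTREF + INTMED + PIE        (identity, exact)
```

Covariate reference values c̄ default to complete-case sample means
(population-averaged reference interaction); both models are fit on the
same complete-case set so the identity holds to machine precision. Defaults
compare a = 1 vs a\* = 0 on the standardized exposure scale with m\* = 0
(the mediator's standardized mean). Correctness is established two
independent ways: symbolic/closed-form properties (additivity for arbitrary
parameters, θ3 = 0 collapsing both interaction components to zero, contrast
reversal behavior) and equivalence with a Monte-Carlo potential-outcome
oracle that simulates Y(a, M(a\*)) contrasts directly — the oracle shares
mediator noise draws across counterfactual levels, and outcome noise
cancels in every contrast, so 10⁶ draws give sub-1e-3 Monte-Carlo SEs.

### 3.2 Inference

Delta-method SEs use analytic gradients of each component with respect to
the stacked coefficient vector (θ1, θ2, θ3 | β0, β1, β2) and a
block-diagonal covariance — the outcome-model and mediator-model
coefficient blocks are treated as independent, the standard approximation
for two separately-fitted models on the same data. Gradients are verified
against central finite differences to 1e-6 relative error in the tests, and
the delta SEs are audited against a nonparametric bootstrap (resampling
subjects, refitting both models). P-values are two-sided normal. A
numerically zero TE flags the estimate and yields NaN proportions rather
than an exception.

### 3.3 Mediation classification

With significance level α = 0.05 and PIE-share threshold 0.20:

- **consistent**: TE significant, |CDE| < |TE|, sign(PIE) = sign(TE), and
  (PIE significant or PIE/TE > 0.20);
- **inconsistent**: PIE significant, |CDE| > |TE|, sign(PIE) ≠ sign(TE);
- **none** otherwise.

The classifier returns the individual rule flags alongside the label
so a classification is always auditable. Fidelity is tested on the shipped
published estimates (all ten replicated mediators classify consistent on
both primary outcomes) and on constructed rows exercising each branch.

### 3.4 Published reference estimates

The ten-protein decomposition table from the source cohort analysis
(N = 3,953) ships as plain CSV (`data/ukb_fourway_reference.csv`, long
format). Printed "<0.001" p-values are stored as 0.001 with an
upper-bound flag; all thresholds used downstream are unaffected. Two
arithmetic identities are acceptance-tested against it: component
additivity within 1e-4 (printed rounding) and recomputation of the PIE
proportion as PIE/TE within 1e-3.

## 4. Mediator PCA

PCA is performed on the correlation matrix (symmetric `eigh`), with strict
Kaiser retention (eigenvalue > 1, overridable). Retained loadings are
varimax-rotated — implemented in-package (~30 lines, SVD-based iteration
with Kaiser normalization, tolerance 1e-8, max 1,000 iterations) because no
factor-rotation library is assumed available. Rotated components are
reordered by explained variance and sign-fixed so each component's largest
|loading| is positive. Scores use the regression method, S = Z·R⁻¹·Λ (with
a pseudo-inverse so singular correlation matrices from collinear mediators
still score), re-standardized to unit variance. Rotation invariants
(communalities, total explained variance) are tested, as is recovery of a
planted two-block structure.

`decompose_pc` runs the four-way decomposition on each component score,
overall and within strata; strata below a minimum size (default 50 complete
cases) are recorded as skipped, and covariates that are constant within a
stratum (e.g., sex inside sex strata) are dropped from that stratum's
design.

## 5. Synthetic cohort generator

### 5.1 Structural model

All structural equations operate on a standardized latent scale:

- Confounder U: standardized z(age) + socioeconomic composite, deliberately
  an exact linear combination of observed covariates so that covariate
  adjustment removes planted confounding *exactly* — null proteins have
  exactly zero adjusted exposure effects in expectation.
- Latent exposure A = c_e·U + √(1−c_e²)·ε (unit variance).
- Observed LE8 total = clip(531.1 − 93.1·A, 0, 800), using the source
  cohort's printed mean and SD. Clipping affects ≈0.2% of draws; its
  attenuation of recovered coefficients is well inside the acceptance
  tolerances (verified empirically by the parameter-recovery test).
- Mediators M_j = α_j·A + c_m·U + s_j·η_j, where η_j is unit-variance
  block-equicorrelated noise (shared block factor, configurable ρ and block
  size) and s_j is auto-balanced (s_j² = 1 − α_j² − c_m² − 2α_j·c_m·c_e) so
  each mediator has unit *population* variance and planted per-SD
  coefficients survive within-sample standardization.
- Latent outcome = γ·A + Σβ_j·M_j + θ3·A·M_0 + c_y·U + σ_y·ε.

### 5.2 Observed scales and realism

Raw outcomes are affine maps of the latent outcome using printed
tract-averaged means/SDs, with sign conventions matching the direction in
which pathology moves each metric (FA and ICVF decrease with worse health;
MD, ISOVF, OD increase). `Cohort.latent_outcome()` inverts the map so
recovery tests work on the planted scale. The generator also emits raw LE8
component inputs with realistic marginals (to exercise the scoring path),
demographics with plausible distributions, a polygenic-risk tertile, and
optional MCAR missingness (deterministic by seed).

Limits: the generator is a linear-Gaussian world — no nonlinearities,
no mediator–mediator causal paths (only noise correlation), a single
planted interaction (on M_0), MCAR rather than informative missingness, and
confounding that is fully observable. These are the assumptions of the
estimators being validated; the generator is an oracle for those estimators,
not a demographic simulation of the source cohort.

### 5.3 Planted truth and recovery

Every generated cohort carries a truth sidecar (α, β, γ, θ3, confounder
strengths, mediator list, outcome scale maps). Acceptance-level recovery
checks: the screen selects exactly the planted set in ≥95% of seeds while
the all-null proteome keeps Bonferroni family-wise error at its nominal
level; across 200 seeded cohorts the mean estimated PIE recovers the
planted product α·β = 0.12 within 3 Monte-Carlo SEs with delta-method CI
coverage in [92%, 98%]. A note on multiplicity: with several correlated
planted mediators, a *single-mediator* decomposition of one of them
absorbs its siblings' paths and legitimately exceeds α·β; exact recovery is
therefore checked on single-mediator cohorts.

## 6. Pipeline and reproducibility

`run_pipeline` is a pure function of (inputs, config, seed): seven stages,
plain TSV/CSV/JSON artifacts, a sequential model-id audit log, and a run
report. Re-running with the same inputs is byte-identical (tested). The
screen stage applies a configurable gate: the |effect| > 0.20 filter
engages only when the Bonferroni-significant set exceeds `screen_gate`
(default 500), mirroring a screen that only needs the effect-size filter
when the significant set is large. All randomness flows through
`numpy.random.default_rng(seed)`; nothing reads global RNG state.

## 7. Numerical choices, in brief

- QR with column pivoting for rank checks (names offenders; tolerance
  scaled to the design norm).
- Single pseudo-inverse for the vectorized screen; per-protein residual
  variances for exact classical SEs.
- `eigh` on the correlation matrix for PCA (symmetric, stable), pseudo-
  inverse for regression scores.
- Analytic delta-method gradients with a finite-difference verification
  path kept in the package (`numeric_gradient_check`) rather than only in
  tests.
- Strict inequalities at all selection/classification thresholds, so
  boundary cases are excluded deterministically.
- ddof = 1 throughout for sample SDs.
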