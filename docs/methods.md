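# Methods

## Model

Drug disposition is linear and time-invariant: a depot compartment with
first-order absorption (`ka`, 1/h) feeding a central compartment with
first-order elimination (`CL/Vc`), optionally exchanging with one or two
peripheral compartments (`Q_i`, `Vp_i`). All parameters are apparent
(bioavailability-scaled). Because the system is linear, the concentration
under any dose history is the superposition of time-shifted single-dose
profiles, and a missed dose simply contributes nothing — this is what makes
scenario-wise simulation cheap and exact.

The one-compartment profile uses the Bateman closed form
`C(t) = Σ_d F·D·ka / (Vc·(ka − ke)) · (e^{−ke(t−t_d)} − e^{−ka(t−t_d)})`
over taken doses. Multi-compartment profiles use one eigendecomposition of
the full (depot + disposition) rate matrix per individual; the central
amount after a unit depot bolus is `Σ_k c_k e^{λ_k Δt}` with coefficients
reused across doses and time points, so a 2000-individual × 120-time-point
cohort is a single vectorised evaluation. Terminal half-life is
`ln 2 / λ_z` with `λ_z` the smallest-magnitude eigenvalue of the
disposition matrix (depot excluded).

Numerical edge cases: when `|ka − ke|/ke < 1e−8` the Bateman form is
replaced by its analytic limit `F·D·ka·t·e^{−ka t}/Vc`; if an
eigendecomposition is ill-conditioned (coincident rate constants, condition
number > 1e10) `ka` is nudged by 1e−7 relative for the affected rows; tiny
negative residue from the complex arithmetic is clipped at zero. The test
suite cross-checks closed form, eigendecomposition and an independent ODE
integration to 1e−6 relative tolerance.

## Packaged model presets

Four theoretical presets span the sensitivity analyses (values in L, L/h,
1/h; proportional residual variance σ² = 0.04 throughout, i.e. ~20% CV
measurement noise):

| preset          | structure | ka  | CL/F | Vc/F | Q1/F | Vp1/F | Q2/F | Vp2/F | t½ (h) |
|-----------------|-----------|-----|------|------|------|-------|------|-------|--------|
| `one_cmt`       | 1-cmt     | 0.5 | 3    | 100  | –    | –     | –    | –     | 23.1   |
| `two_cmt`       | 2-cmt     | 0.5 | 10   | 100  | 5    | 100   | –    | –     | 23.7   |
| `three_cmt`     | 3-cmt     | 0.5 | 2.5  | 10   | 2    | 25    | 1.2  | 20    | 24.2   |
| `one_cmt_short` | 1-cmt     | 0.5 | 2.15 | 25   | –    | –     | –    | –     | 8.1    |

Default between-subject variability is 40% CV on every structural
parameter, with 20% and 60% used for the small/large-variability analyses.
The default regimen is 200 mg once daily for 3 days; three observation
strategies (`non_dot`, `dot_one_dose`, `dot_two_dose`) give 8, 4 and 2
adherence scenarios with equiprobable priors (0.125, 0.25, 0.5).

## Virtual cohorts — what is and is not emulated

`η` is drawn i.i.d. per parameter and individual: between-subject
variability is implemented as *lognormal* (`P·e^η`, `ω = CV/100`), the
standard pharmacometric reading of a CV-parameterised ω²; an
additive-normal reading would produce negative clearances with
non-negligible probability at 60% CV. No IIV correlation, no
inter-occasion variability (beyond the structured occasion-bioavailability
effect in the antimalarial layer), no parameter-uncertainty layer, and no
model misspecification are simulated. Residual error is applied to every
simulated observation — including the reference sample used to derive
percentile cutoffs, since real cutoffs would be derived from (and applied
to) assay-noisy measurements. Each scenario's cohort is an independent
draw (one child seed per scenario, spawned deterministically from the run
seed, so adding scenarios never perturbs existing draws); a consequence is
that "specificity ≡ 1 − percentile" holds by construction while
sensitivities carry Monte-Carlo noise of order 1/√(2000·scenarios).
Passing tests therefore demonstrate internal consistency of the framework
under an exactly-known PK model, not robustness to the model being wrong —
the dominant practical risk in field use.

All cohorts share a time grid referenced to the *scheduled* last dose
(48 h for the daily 3-dose course), including scenarios in which that dose
is missed: "x hours after the last dose" is otherwise undefined for
missed-dose scenarios, and only the scheduled-time convention makes
concentrations comparable across scenarios at one clock time.

## Classification rules and tie conventions

Percentile method: cutoffs are empirical quantiles with linear
interpolation between order statistics (the numpy default; at n = 2000 the
estimator choice moves cutoffs by < 0.1 percentile point). A concentration
*strictly below* the cutoff is poor adherence; ties count as full — the
conservative direction, which also makes the false-positive count exactly
`percentile/100 · n` on the derivation cohort. The percentile search uses
the 5–95% grid in 5% steps, breaking Youden ties toward the lower
percentile (higher specificity). ROC curves add the 0 and 100 grid
anchors plus the (0,0)/(1,1) corners and integrate by trapezoid.

Bayesian method: bins are the 5,10,…,95 percentiles of the *pooled*
concentrations (all scenarios), half-open `[edge_b, edge_{b+1})` with
edge values in the upper bin; conditionals are raw per-scenario bin
fractions with no smoothing. A bin empty under every scenario returns the
prior (flagged in the log). Posterior argmax ties go to the full-adherence
scenario, then the lowest scenario index. For regimens with many
unobserved doses (e.g. a 6-dose course: 64 scenarios) the machinery works
but per-scenario bin masses become noisy at 2000 individuals each; the
percentile method is the practical choice there.

LOQ handling: a censoring level is imposed as the corresponding empirical
percentile of the full-adherence observations; censored observations are
set to zero (below every admissible cutoff, hence always called poor), and
any cutoff whose value falls below the LOQ is raised to the LOQ and
flagged non-evaluable. The "impact is small below 20% censoring" claim is
qualitative; the packaged test bounds the AUC drop at 20% censoring by
0.04, our own margin for a quantity that sits near 0.03 with Monte-Carlo
wobble.

## Antimalarial covariate layer

Clearance-like parameters scale as `(weight/70)^0.75`, volumes as
`(weight/70)^1.0` (conventional allometry; exponents are configurable
because the pooled source models do not travel with this package).
Elimination clearance is additionally multiplied by the maturation
fraction `age^h / (age^h + MF50^h)` with MF50 = 0.575 y and h = 5.11
(so 50% of adult clearance at 0.575 y and 95% at ~1.02 y); relative
bioavailability compounds by +23.7% per dosing occasion
(`F·1.237^(occasion−1)`); pregnancy multiplies `ka` by 1.352. Doses come
from editable weight-band tables (WHO-style bands; per-administration mg).

Cutoff tables simulate 2000 fully adherent individuals per covariate
profile and report the requested percentile of the day-`d` observed
concentration in ng/mL (internal mg/L × 1000). All bodyweight rows reuse
one child seed — common random numbers — so cutoffs vary smoothly and
monotonically within a dose band (concentration falls as weight rises at
fixed dose) and jump upward at band boundaries; with independent seeds the
~2% Monte-Carlo noise per row would mask that structure.

The packaged `piperaquine_like` and `lumefantrine_like` configurations are
synthetic stand-ins: they carry the published covariate effect sizes on
generic disposition kinetics with realistic terminal half-lives (~21 d and
~3.8 d). Their cutoff values are illustrative only; the configuration
schema accepts a published pooled parameter vector for real use.

## Problem sizes and determinism

The packaged analyses use 2000 individuals per scenario (the study-design
cohort size) on an hourly grid to 72 h after the scheduled last dose;
the full test suite runs in a few seconds and the acceptance script in
under a minute on one core. Smaller cohorts (200–500) are used where a
test only checks a structural property, not a rate. Every stochastic entry
point takes a seed; one run seed spawns per-scenario child seeds via
`numpy.random.SeedSequence`, and identical seeds give bit-identical
cohorts, CSVs and JSON.

## Known limitations

* The time-to-peak convention is genuinely ambiguous for multi-dose
  courses. The package measures each individual's peak after the final
  scheduled dose on a dense grid; the population median is ≈4.8 h for the
  base model (typical-profile peak 4.8 h, steady-state peak 4.6 h,
  single-dose peak 6.0 h). Reported "median Tmax" values near 4.3 h are
  reproducible from these profiles only under other conventions (e.g. the
  peak of the population *mean* curve at high variability), so
  peak-time comparisons should state the convention explicitly.
* Equiprobable scenario priors and prevalences are an assumption of
  convenience; informative priors can be supplied but nothing estimates
  them.
* No partial or mistimed doses — a dose is taken on schedule or missed.
* Nonlinear elimination, transit-compartment absorption and enterohepatic
  recirculation are out of scope; first-order absorption stands in for
  transit chains, which mainly matters before the absorption phase ends.
* Classification quality is reported in-sample (cutoffs applied to the
  cohorts that produced them), matching the framework's intended use of
  simulation-derived cutoffs applied to comparable patients; there is no
  cross-validation layer.
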