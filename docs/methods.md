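# Methods

## Structural and covariate model

Gentamicin kinetics are modelled as a single well-stirred compartment with
first-order elimination.  For an infusion at rate `R` over `[t0, t0+T]` with
`k = CL/V`, the concentration contribution is `(R/CL)(1 − e^{−k(t−t0)})`
during the infusion and `(R/CL)(1 − e^{−kT}) e^{−k(t−t0−T)}` afterwards;
multiple doses superpose linearly.  The closed form is exact — no numerical
integration is used anywhere in the pipeline — and is verified in the tests
against brute-force integration of the mass balance (`solve_ivp`, LSODA,
rtol 1e-10) to 1e-6 relative error.

Individual clearance and volume derive from three covariate-scaled
parameters:

* `CL = CLm·(BW/70) + fr·CLcr` with `CLcr` the Cockcroft–Gault creatinine
  clearance.  We use the SI-unit form `CLcr = F·(140 − age)·W/Scr` (Scr in
  µmol/L) with sex factor `F` = 1.23 (male) / 1.04 (female) and total body
  weight by default; the weight metric (BW | LBM | LBMc) is configurable
  because clinical implementations differ.  `CLcr` is converted ml/min →
  L/h at its single point of use.  Ages ≥ 140 y clamp `CLcr` to 0 with a
  warning rather than going negative.
* `V = Vd·LBMc`.  Lean body mass uses the sex-specific quadratic
  `LBM = 1.10·W − 128·(W/H)²` (male) / `1.07·W − 148·(W/H)²` (female, H in
  cm), and the fat-distribution correction adds back a fraction
  `f_fat = 0.4` of the fat mass: `LBMc = LBM + f_fat·(W − LBM)`, capped at
  `W`.  Both the coefficients and `f_fat` are conventional defaults and are
  exposed as configuration, since published variants of these equations
  differ.
* Optional BSA normalisation of `CLcr` (reporting only) uses Du Bois,
  `BSA = 0.007184·W^0.425·H^0.725`, the form most common in Dutch clinical
  software.

Time-varying serum creatinine is handled as piecewise-constant (last
observation carried forward).  The clearance entering a course's fit is
evaluated at the first dose time; a creatinine series that starts after the
requested time raises an "incomplete record" error.

The residual error model is the assay polynomial `SD(C) = 0.0766 +
0.0006·C + 0.0064·C²` mg/L (EMIT).  Concentrations at or below the 0.2 mg/L
lower limit of quantification are flagged and excluded from fitting by
default; a `half_loq` policy retains them at 0.1 mg/L.  Residual weights
evaluate the assay SD at the observed concentration by default ("the
measuring error over the range of existent serum levels"); evaluating at
the predicted concentration is available as configuration.

## Population distributions

Between-subject variability is log-normal.  Priors are stated as arithmetic
mean ± SD and converted with the exact moment relations
`ω² = ln(1 + (SD/mean)²)`, `ln µ = ln(mean) − ω²/2`, so the stated mean is
the distribution mean and `e^{ln µ}` its median.  Three presets ship as
JSON: `icu` (0.277±0.138, 0.899±0.417, 0.335±0.104), `standard`
(0.225±0.113, 0.727±0.471, 0.273±0.082) and `endocarditis` (CLm fixed at
0.277, fr 0.698±0.358, Vd 0.312±0.076), in units of L/h/70 kg BW,
(dimensionless) and L/kg LBMc respectively.

Each parameter carries an estimation setting: `Bayesian` (estimated per
individual; population mean/SD updated during population fitting), `FPB`
(estimated per individual against a never-updated prior) or `Fixed` (held
at the population value, SD treated as 0).  A free parameter whose prior
log-SD is numerically zero is held at the prior median, which makes
`FPB` with SD → 0 coincide exactly with `Fixed`.

## MAP individual estimation

For one course the objective is

```
O(θ) = Σ_j (Cpred(θ, t_j) − Cobs_j)² / SD(Cobs_j)²
     + Σ_p (ln θ_p − ln µ_p)² / ω_p²
```

minimised over the log-parameters (positivity by construction) with a
Levenberg–Marquardt least-squares solver (tolerances 1e-12), starting at
the prior medians with up to 5 jittered restarts on non-convergence (the
jitter stream is keyed to the course id so results are independent of
cohort order).  Posterior spread is the Gauss–Newton Laplace approximation:
since `O` is −2× the log posterior up to a constant, the log-scale
covariance is `(JᵀJ)^{-1}` at the optimum.  A record with no usable
observations returns the prior medians with zero WSS.

## ITSB population fitting

Stage 1 MAP-fits every course against the current population parameters;
stage 2 re-estimates each `Bayesian` parameter's population distribution
from the individual estimates on the log scale:

```
µ ← mean(ln θ̂_i)
ω² ← var(ln θ̂_i) + mean(s_i²)        (shrinkage-corrected, default)
```

where `s_i²` is the individual posterior log-variance.  Adding the mean
posterior variance is the standard iterated-two-stage refinement that
compensates the shrinkage of MAP point estimates toward the prior; the
naive update (sample variance only, `shrinkage=False`) is available for
comparison.  Cycles repeat, each using the previous population parameters
as priors, until every updated mean and SD moves by less than a relative
tolerance of 1e-4 (SD changes measured relative to the mean, so SDs
collapsing toward zero still converge) or 200 iterations.  The cohort is
sorted by course id on entry, making results bit-identical under
permutation of the input order.

The traced objective is the quantity the active update descends: for the
naive update the joint −2 log posterior (WSS plus Gaussian normalising
constants), on which the two stages are exact coordinate descent and the
trace is monotone to rounding; for the shrinkage update the
Laplace-approximate marginal −2 log likelihood, which the EM-like update
decreases up to the approximation error (small cohorts, or drifts along an
unidentifiable-variance ridge, can raise it by ~1e-4 relative).  Three
consecutive substantial increases (beyond 1e-8 relative for the naive
update, 1e-3 for shrinkage) raise a divergence error carrying the trace.
Raw ΣWSS alone is monotone in neither mode, because updating the
between-subject SDs re-weights the prior penalty.

## Goodness of fit and model selection

Degrees of freedom follow the measurements-minus-parameters convention:
`df = (number of concentration measurements) − (estimated population
parameters) − (estimated individual parameters)`, where each `Bayesian`
parameter contributes two population parameters (mean and SD) and each
course contributes one individual parameter per `Bayesian`/`FPB`
parameter.  `ΣWSS/df` sums both WSS components over courses.

The AIC is

```
AIC = Σ_obs [wres² + ln(2π·SD²)] + Σ_prior [wres² + ln(2π·ω²)]
    + 2·(n_population + n_individual)
```

i.e. the joint −2 log posterior density plus 2 per estimated parameter,
using the same parameter count as the df.  Penalising individual parameters
is deliberate: without it a candidate with per-course parameters that the
data cannot identify (for instance an individual metabolic clearance
estimated from 3–4 samples) is never charged for them, and a collapsing
between-subject SD can make the prior normalisation terms arbitrarily
favourable.  Absolute AIC values are implementation-defined — the Gaussian
constants and the penalty convention differ between programs — so only
differences between candidate settings fitted to the same data are
meaningful, and the tests assert rank order only.

The population bootstrap resamples courses with replacement, re-runs the
full ITSB fit per replicate and reports percentile 2.5/97.5 intervals for
each parameter's mean and SD; failed replicates are dropped and counted,
with more than 10% failures raising an error.

## External validation

Predictions are generated in one of two modes.  `posterior` (default)
mirrors one-cycle Bayesian evaluation of predictive power: each validation
course is MAP-fitted once against the candidate model — whose population
values never move — and its observations are predicted from the fitted
parameters, all of a course's samples being used jointly.  `a_priori`
predicts from the population medians and ignores the measured values
entirely.  Prediction errors are `PE = 100·(Cpred − Cobs)/Cobs` %; MDPE is
their median (bias) and MDAPE the median of their absolute values
(precision), with the even-n median taken as the midpoint of the two
central order statistics.  95% CIs use the plain percentile bootstrap
(10,000 replicates by default), resampling individual prediction errors;
resampling whole courses is available as an option.  No bias-correction
(BCa) is applied.

## Simulation and forecasting

A priori simulation draws `(CLm, fr, Vd)` from the population log-normals
(`Fixed` parameters held constant), maps each draw through the covariate
model and the closed-form kinetics, and reports the pointwise median and
2.5/97.5 percentiles.  The band reflects parameter variability only;
adding assay noise per profile is a flag.  Bayesian forecasting MAP-fits
the record and draws from the multivariate log-normal Laplace approximation
at the MAP (full Gauss–Newton covariance, Cholesky sampling) — not MCMC,
matching desk-scale TDM practice.  With no usable observations the
forecast reduces exactly to the a priori simulation under the same seed.

Dose recommendation exploits dose linearity: with the peak operationalised
as the end-of-infusion concentration of the template's last dose (steady
state once enough doses are scheduled; a post-infusion sampling offset is
configurable), the advised dose is `reference_dose · target_peak /
reference_peak` with the target at the midpoint of the 9–12 mg/L window
(10.5 mg/L).  The predicted trough one dosing interval after the last dose
start is checked against the trough ceiling (default 0.5 mg/L, configurable
up to 1 mg/L); a trough above the ceiling flags the interval as
insufficient rather than silently lengthening it.

## Synthetic cohorts

The generator emulates the study design so the pipeline is testable without
patient data.  Demographics are truncated normals inside the published
ranges with SD = (range width)/4 (modeling cohort: age 69.3 y [32–92],
weight 76.2 kg [46–121], height 173.9 cm [149–193], 21F/44M; validation
cohort: 63.4 y [30–88], 80.3 kg [65–90], 177.7 cm [169–195], 3F/11M).  A
single serum creatinine per course is back-calculated from a target
creatinine clearance drawn inside the published range (modeling 64.3
[8.7–157.5], validation 75.5 [28.4–181.5] ml/min) by inverting the
configured Cockcroft–Gault variant.  Courses receive 2–7 once-daily 3 mg/kg
30-minute infusions (dose rounded to 1 mg).  Sampling is fixed-count so the
cohort totals are exact (221 samples over 65 courses; 30 over 14): samples
are distributed as evenly as possible across courses and drawn from
successive dosing occasions as a "peak" 0.5 h after end of infusion (t =
1 h into the interval) and a mid-interval sample 4 h after end of infusion
(t = 4.5 h), mirroring common TDM practice.  True individual parameters
are drawn from the generating population model; observations add
`N(0, SD(C_true))` assay noise and are clipped at the LOQ with a flag.  A
hidden truth table accompanies every cohort for recovery scoring
(`bias = (estimated population mean − truth mean)/truth mean`; RMSE of the
relative individual errors).

What the generator does not emulate: real sampling-time irregularity,
time-varying renal function within a course (supported by the model but not
generated by default), missing data, dialysis, or assay-platform mixtures.
Passing tests therefore demonstrate correctness of the estimation machinery
under the stated design, not robustness to those real-data features.

## Problem sizes and numerical choices

The test suite and the acceptance script run the study at its native scale
(65/221 modeling, 14/30 validation) with scaled-down replicate counts where
a full-size bootstrap would add nothing but wall time: 100 population
bootstrap replicates (from 1000) in the acceptance script and 2000
validation-bootstrap resamples (from 10,000) in the coverage check.
Monte-Carlo bands use 20,000–50,000 draws.  The MAP-vs-grid oracle refines
a 400×400 log-grid three times around the incumbent argmin, giving a final
grid resolution far below the 0.1% comparison tolerance.

## Known limitations

* CLm and fr are not separately identifiable from a single course (the
  creatinine clearance is constant within a course), so individual CLm
  estimates under the ICU/standard priors are prior-dominated; population
  fitting of CLm on cohorts without very poor renal function drifts along
  this ridge, which is exactly why the endocarditis structure fixes CLm.
* The Laplace posterior is a log-space Gaussian; for strongly ridged
  posteriors its median profile can deviate a few percent from the MAP
  profile at late times.
* Absolute AIC and ΣWSS/df values are not comparable across programs; only
  within-pipeline rankings are meaningful.
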