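# Methods

## The formula chain

All pressure inputs are brachial cuff pressures in mmHg; inside the
formulas, pressures and pressure differences are converted to Pa
(× 133.322).  Blood density ρ defaults to 1050 kg/m³ and the reference
pressure P_ref to 100 mmHg.  PWV is the heart-ankle pulse wave
velocity, path length (m) over total transit time tb + tba (s).

The package implements the chain

* β = 2ρ·PWV²·ln(SBP/DBP)/ΔP (Bramwell–Hill form, ΔP in Pa),
* CAVI = a·β + b,
* β₀ = β − ln(DBP/P_ref),
* CAVI0 = 2ρ·PWV²/DBP_Pa − ln(DBP/P_ref),

together with the conversion

* CAVI0 = [(CAVI − b)/a]·(SBP/DBP − 1)/ln(SBP/DBP) − ln(DBP/P_ref),

whose final log term is written in DBP precisely so that the
conversion composed with the CAVI formula reproduces the direct CAVI0
formula identically — an algebraic identity the test suite checks to
1e−10 over random grids of (SBP, DBP, PWV, a, b).  A consequence worth
stating: CAVI0 obtained by conversion is independent of the device
constants (a, b), so unknown proprietary scalings do not affect any
cross-index conclusion.

The device constants a and b are proprietary and unpublished; the
library defaults a = 1, b = 0 give the raw Bramwell–Hill β as the CAVI
scale.  Every identity above holds for any a > 0, b, so no result in
this package depends on their values.  MAP is computed as DBP + PP/3,
the standard sphygmomanometric convention.  The degenerate case
SBP = DBP raises an error rather than returning the analytic limit
2ρ·PWV²/DBP_Pa; the limit is exercised in tests at SBP = DBP·(1+1e−6).

## The synthetic cohort

No subject-level data are available for the population this generator
emulates, so the generator reconstructs its *joint structure* from
published two-stratum summaries (threshold 70 years):

* **Age** ~ Normal(68.3, 14.4²) truncated to [40, 96].  Truncation
  shrinks the realized SD to ≈ 12.5 years; all calibrations below use
  the truncated moments.
* **DBP** = α₀ + α₁·age + N(0, σ_ε²), clipped to the observed range
  [55, 109] mmHg (clipping can be disabled).  The slope is calibrated
  in closed form, α₁ = r·σ_ε/(σ_age·√(1−r²)), to the target
  correlation r = −0.464, with σ_age the truncated age SD; the
  intercept anchors the mean DBP at 81.2 mmHg.  σ_ε defaults to
  9.48 mmHg, chosen so the marginal DBP SD is ≈ 10.7 mmHg.
* **Pulse pressure** ~ Normal with mean and SD linearly interpolated
  in age between the stratum anchors (54.9 ± 13.18 at age 56.86,
  60.07 ± 14.53 at 80.79; clamped outside), floored at 10 mmHg.
  SBP = DBP + PP; PP is drawn independently of DBP within stratum, as
  no PP–DBP dependence is documented for the reference population.
* **Sex, BMI, waist, comorbidity flags** are drawn per stratum
  (male probability 0.28/0.44; BMI 31.38 ± 4.82 / 25.84 ± 5.68 kg/m²;
  waist 103.6 ± 13.88 / 97.18 ± 15.19 cm; hypertension 0.62/0.78,
  diabetes 0.21/0.29, dyslipidemia 0.74/0.58, smoking 0.24/0.35).
  Flags are independent Bernoulli draws: the analyses this package
  targets never condition on them, so no flag–index coupling is
  modeled.

A single NumPy Generator keyed by the config seed drives every draw,
in the fixed order age → sex → BMI → waist → DBP noise → PP → flags →
index/PWV noise, so cohorts are reproducible across runs and versions.

### Regression mode

CAVI0 and CAVI are drawn from the generating planes

* CAVI0: (−30.301, 0.682, 0.306, −0.005) for (intercept, age, DBP,
  age×DBP),
* CAVI: (−4.16, 0.175, 0.072, −0.001),

plus Gaussian noise.  The CAVI0 noise SD is calibrated to a target
model R² of 0.508 via σ² = Var(μ)·(1−R²)/R², with Var(μ) estimated on
a 100,000-subject pilot covariate sample drawn from a fixed internal
seed (so calibration does not consume the cohort's random stream).
The CAVI noise SD defaults to the CAVI0 noise SD scaled by
0.062/0.176: the two reference models share a design matrix, so the
ratio of their residual SDs equals the ratio of any coefficient's
standard errors, and the age-term SEs are 0.062 and 0.176.  Either
arm accepts an explicit `noise_sd` or `target_r2` instead.

### Mechanistic mode

PWV = c₀ + c₁·age + N(0, σ_pwv²) with defaults c₀ = 4.8 m/s,
c₁ = 0.045 m/s per year, σ_pwv = 0.6 m/s — values chosen (not
estimated from any dataset) so that the resulting CAVI lands in the
7.5–10.5 range typical of adults aged 40–96; they are synthetic
defaults, not published physiology.  Given age, PWV is independent of
DBP, so any fitted age×DBP interaction on an index arises purely from
the index formula's pressure dependence.  This is the package's
mechanistic embodiment of the headline phenomenon: because CAVI0
divides by DBP, the age-driven DBP decline induces a strong negative
interaction on CAVI0, while CAVI (log pressure ratio, any a, b)
acquires one roughly half as large — real, but often below the
detection threshold of a 191-subject study.  Negative PWV draws
(possible only under extreme configs) are clipped to zero with a
logged warning.

### What the generator does not emulate

Biochemical covariates, longitudinal trajectories, missing data,
comorbidity–stiffness coupling, measurement error on pressures, and
any nonlinearity of the true index–age relationship.  Passing tests
therefore demonstrate that the *pipeline* recovers what was put in
under realistic marginal structure — not that the generating models
are true of any real population.

## Statistical pipeline

* **t test**: pooled-variance Student by default (Welch by flag).
* **Mann–Whitney U**: exact null distribution for tie-free combined
  n ≤ 20 (verified against exhaustive enumeration in tests), otherwise
  the normal approximation with tie and continuity corrections.  A
  completely tied comparison returns U = n₁n₂/2, p = 1.
* **2×2 chi-square**: Pearson with Yates continuity correction
  (clamped at |O−E|), df = 1.  On the reference comorbidity tables the
  dyslipidemia and diabetes rows reproduce the published p-values to
  three decimals, which is what fixed the correction choice.
* **OLS**: fitted via statsmodels with classical (homoskedastic)
  standard errors; two-sided p from t with n−p df.  Terms are
  {intercept, age, dbp, age×dbp} plus optional {sbp, sex (male = 1),
  bmi}.  Rank deficiency raises an error naming the collinear columns.
  ANOVA is sequential (Type I) on the model's term order.
* **Permutation inference**: Freedman–Lane per term — fit the reduced
  model without the term, permute its residuals, add them back to the
  reduced fitted values, refit the full model, and compare |t*| to
  |t_obs|; p = (1 + #{|t*| ≥ |t_obs|})/(B + 1).  B ≥ 99 is enforced
  (coarser resolution is useless at α = 0.05); the B columns are
  solved in one matrix product per term.  Raw response permutation is
  available by flag.  The scheme is the literature-standard choice for
  linear-model coefficients; exact agreement with any particular
  external permutation implementation is not claimed.  Validity is
  checked by simulation: under a true null the p-values are uniform
  (KS test over 500 replicates of n = 50 with B = 199).
* **Crossover**: age* = −β_dbp/β_int, value = β₀ + β_age·age*.  At
  age* the fitted prediction is DBP-independent to numerical
  precision.  Reported crossover quantities use the 3-term model.
* **Strata**: the descriptive comparison splits at 70 years; quartiles
  use linear interpolation (the inclusive-median convention).  The
  trend analysis scores decades 40–49 … 80–89, 90+ ordinally and
  regresses the index on the score, optionally adjusting for DBP.
* **Multiplicity**: no multiple-testing correction anywhere; α = 0.05
  two-sided throughout, matching standard practice for this kind of
  single-cohort descriptive study.

## Problem sizes and numerical choices

Parameter-recovery and calibration checks run on one shared
200,000-subject regression-mode cohort (seed 1): at that size the
Monte-Carlo SEs of the age and DBP slopes are ≈ 0.006 and 0.005, so
recovery is asserted within ~2 SEs, and the realized DBP–age
correlation and model R² are asserted within ±0.01 of their calibrated
targets.  The mechanistic effect-modification contrast is evaluated on
40 independent cohorts at the study-scale n = 191 and judged on pooled
evidence (Stouffer-combined z for the CAVI0 interaction; mean |t|,
|coefficient| and p for the attenuated CAVI interaction) rather than
on a single stochastic replicate.  Permutation-validity simulations
use 500 replicates × B = 199 × n = 50.

Floating-point notes: the CAVI→PWV inverse is exact to 1e−10 with
a = 1, b = 0 but limited by cancellation in (CAVI − b)/a for small β
under general device constants (tested at relative precision);
crossover is undefined (raises) when the interaction estimate is
exactly zero.

## Known limitations

The published prediction-surface values and crossover (≈ 64 years,
value 13.5) for the reference model are not exactly recoverable from
its rounded printed coefficients (which give 61.2 and 11.44); the
package therefore validates the surface qualitatively — sign pattern,
ordering and crossover bracket — and makes no numerical claim about
those two figures.  The published smoking-row chi-square p (0.120)
matches neither the Yates-corrected (0.125) nor the uncorrected
(0.091) statistic on the printed counts and is not reproduced.
Robust/clustered standard errors, model selection and survival
analysis are out of scope.
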