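# Methods

This note documents the models implemented in `somascan`, the choices made
where conventions diverge, what the synthetic cohort generator does and
does not emulate, and the package's numerical conventions.

## Somatotype components

A somatotype is a triple (endomorphy, mesomorphy, ectomorphy) on an
open-ended positive scale. All three components are floored at 0.1, the
conventional minimum of the scale: the endomorphy cubic is negative near
zero skinfold sum, the mesomorphy linear form goes negative for tall
gracile builds, and the middle ectomorphy branch (0.463·HWR − 17.63)
evaluates just below 0.1 for HWR in [38.25, ≈38.293). Every floor event is
logged at INFO level so cohort runs leave an audit trail. Raw component
values are kept at full floating precision everywhere; rounding to whole
numbers (components, HWR) and to two decimals (BMI) happens only in the
presentation layer (`io.results_frame`), because statistics computed on
pre-rounded values would be systematically coarsened.

### Manual pathway

Endomorphy uses the three-skinfold cubic with the 170.18/height stature
correction; mesomorphy corrects each limb girth by the overlying skinfold
(mm → cm, divide by 10) before weighting; ectomorphy is the three-branch
piecewise function of HWR = height/weight^(1/3) with inclusive lower
bounds. The HWR is **not** rounded before the branch test: rounding first
is a possible reading of how legacy applications displayed values, but it
would move subjects across branch boundaries by display precision, which
is not defensible statistically.

### Scan pathway

Optical scanners miss two inputs, each replaced by a predictive model:

* **Stature** — linear in the floor-to-C7-vertebra landmark height. The
  shipped default (slope 0.1039 cm/mm, intercept 19.39 cm, R² 0.9218,
  Sy.x 2.535 cm, n 117) is a calibration for one scanner and population;
  `fit_height_model` refits it from paired (C7, measured height) data and
  reports the n−2 residual SE and a 95% t-based slope CI (the t form
  matches the symmetric interval convention; with n ≥ 30 it is
  indistinguishable from a normal interval).
* **Relative fatness** — the US Navy circumference equations (metric,
  base-10 logarithms), converted at 5% body fat per endomorphy unit. The
  formula can stray outside physiology for extreme inputs, so BF% is
  clamped to [0, 75] with a logged clamp event rather than raising: a
  clamped subject in a 117-row cohort run is recoverable, an aborted run
  is not. Log-domain violations (male waist ≤ neck; female
  waist + hips ≤ neck) are hard errors and are also enforced at record
  construction so they surface at ingest with a row number.

Scan mesomorphy uses the same linear combination as the manual form but
with uncorrected girths (no skinfolds exist in a scan). The hybrid mode
(`breadth_source="manual"`) substitutes caliper bone breadths into the
otherwise scan-based computation — useful because breadth landmarks are
the scanner measurement most prone to systematic error, and the hybrid
isolates that one error source.

Units are fixed package-wide: cm everywhere except skinfolds (mm) and the
C7 landmark (mm, making the ~0.104 cm/mm slope dimensionally natural).
Conversion happens once, at table ingest, driven by declared per-column
units — never by header guessing, since a silently swapped waist/hips
column would corrupt the body-fat equation invisibly.

## Classification

The 13-category scheme labels a triple by dominance with two thresholds:
1.0 (central: no pairwise difference exceeds it) and 0.5 (co-dominance and
"balanced" side-pair similarity). Ties exactly at a threshold resolve
toward the more central/co-dominant label (inclusive comparisons), which
makes the classifier total and deterministic; both thresholds are keyword
arguments so alternative readings can be tested. Classification uses
unrounded components by default; a `rounded=True` variant exists for
sensitivity analysis. The somatochart axes are the universal convention
x = ecto − endo, y = 2·meso − (endo + ecto).

## Agreement statistics

Differences are always candidate − reference. Limits of agreement use a
fixed 1.96 multiplier on the sample SD (no small-sample t correction).
The two ICC forms are two-way single-measure: absolute agreement ICC(A,1)
and consistency ICC(C,1), computed from the subjects × methods ANOVA
decomposition (MSR, MSC, MSE) and cross-checked against an independent
implementation in the test suite. SME (standard measurement error) is
pooled SD · √(1 − ICC), reported for both forms; pooled SD is the square
root of the mean of the two per-method sample variances. CV is the
within-subject two-method form, 100·(SD_diff/√2)/grand mean. SEE is the
residual SE of regressing candidate on reference (n−2 denominator) —
note this is a *units-of-the-measurand* regression diagnostic and can
legitimately differ in magnitude from RMSE when between-subject variance
is small relative to noise. Reports always carry both the signed
difference summary (bias direction) and the absolute difference summary
(typical error size); the two answer different questions and published
validation tables mix them.

A failing cell (e.g. ICC undefined because between-subject variance is
zero) is marked with a recorded reason rather than aborting the report.

## Synthetic cohort generator

The generator defines the study conditions under which the package is
exercised: n = 117 with 68 women / 49 men by default. Per-sex
truncated-normal marginals are coupled by a one-factor Gaussian copula (a
single latent body-size factor with fixed per-field loadings scaled by the
`correlation` parameter, default 0.7), giving height–weight–girth rank
correlations around 0.4–0.6 without ever producing an invalid covariance.
The per-sex means/SDs are the package's own choice of a realistic
young-adult cohort, constrained so the 68:49 pooled moments reproduce the
published cohort table (pooled height 171 ± ~9 cm, weight ~69.9 ± ~14 kg,
girths/breadths likewise); tape-measured waist/hip/neck circumferences —
needed by the body-fat equations but absent from the classical skinfold
protocol — are generated as latent variables linear in body mass and
carried alongside the manual records in the `Cohort` container.

The scanner model derives each scan record from its manual counterpart as
value + per-measurement additive bias + Gaussian noise. Default biases are
the published manual-vs-3D mean offsets (cm): waist +1.52, hips +4.00,
biceps +1.02, calf −0.25, humerus +0.22, femur +1.89; default noise SDs
(0.3–1.0 cm) are plausible scanner repeatabilities. The C7 landmark height
inverts the stature regression and adds landmark noise with SD 24.4 mm,
back-solved as Sy.x/slope = 2.535/0.1039 so that refitting the regression
on synthetic data reproduces R² ≈ 0.92 — a calibration, not a measured
value. Note that noise on C7 sits in the *predictor*, so a refit on
synthetic pairs shows the expected errors-in-variables attenuation
(fitted slope ≈ 0.096–0.100); the parameter-recovery simulations in the
tests and acceptance script instead place the noise in stature, matching
the calibration design, and recover the coefficients unbiasedly.

What the generator does **not** emulate: real covariance between trunk
circumferences and skinfolds beyond the shared size factor, non-Gaussian
skinfold skew, posture- or garment-dependent scanner error, and any
mesh-level geometry. Passing tests therefore demonstrate that the
pipeline's equations, plumbing and statistics behave correctly under
controlled bias and noise — not that a particular scanner achieves a
particular agreement on real bodies. In particular the simulated
13-category agreement (~50% under default biases) is a property of the
assumed bias/noise magnitudes, not a reproduction of any empirical
agreement figure.

## Numerical and interface choices

* Validation is at record construction, and violations are hard errors:
  downstream formulas never see a log-domain failure silently. Ingest
  quarantines invalid rows (with row number and reason) instead of
  failing the whole table; rows in = rows accepted + rows rejected always.
* OLS fits go through `scipy.stats.linregress`; ICC/SME/CV/SEE/RMSE are
  implemented directly from their ANOVA/closed-form definitions (a few
  lines each) so they remain independently cross-checkable.
* The BMI assessment bins are the WHO adult cut-offs with half-open
  intervals, lower bound inclusive.
* Simulation sizes in the test suite (cohorts of 24–117, Monte-Carlo
  batches of 200 replicates, property grids of a few thousand points)
  were chosen to make sampling error negligible relative to the asserted
  tolerances while keeping the default suite fast.

## Known limitations

* The Navy equations and the 5%-per-unit conversion are population-level
  approximations; endomorphy from circumferences is the least reliable
  component and systematic trunk-circumference bias propagates into it
  directly.
* The shipped stature calibration is scanner- and cohort-specific;
  applying it to a different scanner or population without refitting will
  bias every height-dependent quantity (ectomorphy, mesomorphy, BMI).
* The 13-category rule thresholds (0.5/1.0) follow the standard scheme;
  category agreement between two methods is sensitive to them near
  boundaries, which is why they are configurable and why statistics are
  computed on unrounded components.
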