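# Methods

This note records the statistical model the package implements, the
choices made where the published description leaves room, and what the
synthetic data do and do not establish.

## LMS z-scoring

A growth reference is stored as (age, L, M, S) knots per measurement and
sex.  For a value `x` at age `t`, L/M/S are interpolated linearly in age
(days) and

    z = ((x/M)^L − 1) / (L·S),     z = ln(x/M)/S  when |L| < 1e−7.

The transform is evaluated as `expm1(L·ln(x/M))/(L·S)` and inverted as
`M·exp(log1p(L·S·z)/L)`, which is numerically continuous through the
`L → 0` limit; the inverse round-trips to well under 1e−6 relative over
the whole plausible range.  The Box-Cox family only attains z-scores with
`1 + L·S·z > 0`; values outside that support raise a domain error rather
than returning a complex or negative measurement.

Ages are handled in days throughout; one month is defined as 30.4375 days
everywhere window logic appears.  Linear-in-age interpolation of L, M and
S independently is the package's choice (standard LMS practice and
monotone-preserving); how the original analysis interpolated routine
measurement ages is not public.

**Synthetic reference.** Licensed national references are not
redistributed.  `synthetic_reference(seed)` builds smooth parametric
curves over 0–30 months at monthly knots: a saturating-plus-linear median
for weight (3.5 kg at birth to ~13 kg at 24 months) and length (50 cm to
~84 cm), mild L/S age trends, a small sex offset, and a seeded smooth
sub-percent perturbation of the medians so distinct seeds give distinct
references.  The BMI median is *derived* as `M_weight/(M_length/100)²`
from the same (perturbed) curves, so a median infant has weight, length
and BMI z-scores of exactly zero and the three references are mutually
consistent; the BMI S is set so that on-reference weight/length variation
induces a BMI z SD near one.  The fixture is a coherent stand-in with
realistic magnitudes, not a clinical standard: absolute z-scores computed
against it are not comparable to UK90 values.

## Conditional weight gain

The conditioning regression of follow-up weight z on baseline weight z is
ordinary least squares with residual SD on the n−2 denominator.  Gains are
standardized residuals, so in the fitting sample they have mean 0, SD 1
(with the n−2 convention) and zero correlation with baseline z — asserted
as invariants on every fitted model in the tests.  Zero baseline variance
or an exact fit raises a degenerate-model error, since the gain is then
undefined.

The conditioning sample is the analysis cohort itself (per equation
sample); an externally fitted `ConditionalModel` can be supplied for
scoring new infants.  The constants the original mobile tool used are not
public, so the shipped default assumes on-reference tracking with a
birth-to-assessment weight-z correlation of 0.65 (intercept 0, slope 0.65,
residual SD √(1−0.65²)) — a mid-range value for infant weight tracking —
and is replaceable via the model config.

## Composite outcome

An infant is outcome-positive when 2-year BMI z exceeds the 91st-centile
z (≈ 1.3408) **and** the conditional birth-to-2-years gain exceeds one
centile band.  One centile band is quantified as 0.67 SD, the spacing of
adjacent major centile lines on UK nine-centile charts (2/3 SD); it is
configurable.  The gain comparator is strict (`>`) by default with an
inclusive option, since published descriptions of the rule use both forms.
When several measurements fall in an eligibility window, the one nearest
the window centre is used.

## Risk equations and banding

The six published coefficient sets and their score-distribution thresholds
are embedded verbatim as frozen constants.  The risk score is the standard
logistic linear predictor (the exponentiated birthweight coefficient of
the 12-month equation reproduces its published development odds ratio,
confirming the functional form).  Banding: probability ≥ t10 (the
threshold placing 10% of the development population above it) is high
risk; between t20 and t10 is medium; below t20 is low.  The published
prose on the medium/low boundary is internally inconsistent as printed;
top-decile = high, decile-to-quintile = medium is the only reading
consistent with "10% as high risk" and is what the thresholds encode.

Assessment windows are half-open in months: [4.5, 7.5) → equation 1,
[7.5, 10.5) → equation 2, [10.5, 13.5] → equation 3; outside 4.5–13.5
months scoring refuses.  Unit conversions: lb × 0.45359237 → kg,
in × 2.54 → cm.  Maternal BMI is used only when both maternal height and
weight are present, switching to the with-maternal-BMI variant.

## Equation development

Logistic models are fitted by Newton-Raphson maximum likelihood
(tolerance 1e−10, max 100 iterations), with Wald standard errors from the
inverse observed information.  Non-convergence and complete or
quasi-complete separation raise explicit errors instead of returning
divergent estimates.  Backward stepwise elimination removes the
highest-Wald-p term at each step until all retained terms have p < α
(default 0.05).  P-values are Wald chi-square tests (block tests for
multi-column terms); the five-level education factor enters as four
dummies removed or retained jointly.  Interactions are eligible for
removal before their main effects (a main effect is frozen while a
retained interaction contains it); ties are broken by removing the
later-declared term, making the path deterministic.  Collinear terms that
add no rank are dropped up front, later-declared first.  Sex is forced
into the final scoring models by default, mirroring the published scoring
equations, but forcing is configurable (the published development models
themselves do not all retain sex).

## Validation

AUC is the Mann-Whitney estimator (ties one half), which equals
exhaustive case-control pair counting exactly — a brute-force pair
counter is the test oracle.  Its CI is DeLong's, from empirical placement
values.  Cut-off diagnostics place the threshold at the ⌈q·n⌉-th largest
score with test-positive meaning score ≥ threshold, so the positive
fraction equals q up to ties; sensitivity/specificity/PPV/NPV come from
the 2×2 table with Clopper-Pearson exact CIs.  PPV/NPV satisfy the Bayes
identity with prevalence on every output (asserted in tests).

Bootstrap internal validation resamples the cohort with replacement at
the original n, re-runs the entire stepwise development per resample, and
summarises: a single-column term enters the summary model when its
bootstrap 95% percentile interval (counting zero in reps where it was
dropped) excludes zero; blocks and forced terms use retention frequency
≥ 50%.  Both rules are interpretations — the original report states the
conclusion, not the procedure.  The summary model is refit on the
original sample and its AUC on the original sample reported, the quantity
the original internal validation compared.  Degenerate resamples are
skipped and counted.

External validation scores a cohort with frozen coefficients and reports
the AUC.

## Synthetic cohorts

**Model mode** draws covariates independently at the development-sample
summary moments — sex ~ Bernoulli(0.49 female), birthweight z ~
N(−0.56, 1.2²), conditional gain ~ N(0, 1) independent of birthweight z
(gains are residuals on birthweight z by construction), maternal BMI ~
N(25.9, 5.6²) truncated to [13, 60], ethnicity/education/smoking/GDM/
preterm at the published rates — and the outcome from the logistic model
with the configured (default published) coefficients.  Prevalence is
emergent, not forced; under the 12-month defaults it lands near 7.5%,
inside the 6–10% band around the reported 8.3%.  Per-window and external
presets adjust the moments to the corresponding published sample
summaries.  Covariates are drawn independently because their joint
distribution is unreported; real cohorts correlate e.g. ethnicity with
maternal BMI, which these cohorts do not reproduce.  The 2-year BMI z in
model mode is a decorative companion variable (correlated 0.5 with the
gain), not the outcome's source.

**Growth mode** draws a latent weight-z process at birth, one assessment
visit (uniform in the equation's window) and ~24 months (±2 months), with
birth↔24-month correlation 0.5 and the AR-consistent √0.5 per leg, maps
it to raw kilograms/centimetres through the inverse LMS transform
(24-month length correlated 0.6 with weight so BMI is realistic), then
rebuilds the entire cohort table from the raw measurements with the same
pipeline a real cohort would use: z-scoring, within-cohort conditioning
regressions, and the composite outcome rule.  Round-tripping the emitted
measurements reproduces the cohort table exactly, and outcomes satisfy
the composite rule by construction.

Consequently, passing tests show that the *pipeline* is correct and that
the published coefficients are mutually consistent with the published
discrimination under a Gaussian-covariate approximation; they cannot
certify performance on real cohort data, whose covariates are neither
Gaussian nor independent.

## Problem sizes and numerical conventions

Parameter-recovery runs use n = 100 000 and discrimination runs
n = 200 000, sizes at which Monte-Carlo error is small against the
published precision while a full run stays within seconds on one CPU;
bootstrap checks use B = 200 at n = 3 000 (B = 1000, the original
protocol, is the API default).  All randomness flows through
`numpy.random.default_rng` seeds; every simulation and CLI command is
bit-reproducible under its seed.  Probabilities are computed in double
precision without clipping; model configs serialise coefficients exactly,
so a save/load round trip reproduces bit-identical probabilities.

## Known limitations

- The synthetic reference is not UK90; z-scores are internally coherent
  but not clinically interpretable.
- The shipped conditioning constants are an assumption (see above);
  scoring sensitivity to that correlation is the main unquantified
  uncertainty when comparing against the original tool.
- Covariate independence in the generators understates real-world
  confounding; stepwise retention frequencies on synthetic data will be
  cleaner than on real data.
- Thresholds are fixed development-sample quantiles; they are not
  recalibrated to a new population unless equations are re-developed.
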