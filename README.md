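# growthrisk

Infant childhood-obesity risk scoring — and the full pipeline for
developing and validating such risk equations — as a Python library with a
thin command-line interface.

## The problem

Greater birth weight and rapid weight gain in infancy are two of the most
consistent early-life predictors of childhood obesity.  A practical
screening tool scores an infant between 4.5 and 13.5 months of age from a
handful of routine inputs (sex, birthweight, current weight, optionally
maternal BMI) and returns a low/medium/high risk band, so that families at
high risk can be offered advice early.

`growthrisk` implements such a tool end to end:

1. **LMS z-scores.** Raw weight/length/BMI are converted to age- and
   sex-adjusted z-scores against a growth reference summarised by the
   Box-Cox *L* (skewness), median *M*, and coefficient-of-variation *S*
   curves: `z = ((x/M)^L − 1)/(L·S)`, with the `log(x/M)/S` limit as
   `L → 0` and linear age interpolation between knots.
2. **Conditional weight gain.** Raw z-score change penalises small babies
   through regression to the mean; the conditional gain is the
   standardized residual of the follow-up weight z regressed on the birth
   weight z — mean 0, SD 1, uncorrelated with starting size by
   construction.
3. **Logistic risk equations.** For three assessment windows (6 ± 1.5,
   9 ± 1.5, 12 ± 1.5 months) and two variants (with/without maternal BMI),
   the risk probability is

   `p = 1 / (1 + exp(−[α + β₁·1(female) + β₂·bw_z + β₃·gain_z (+ β₄·mBMI)]))`

   with the published coefficients embedded as constants.  Probabilities
   are banded against thresholds fixed at the 10%/20% points of the
   development-sample score distribution: top decile = **high**,
   decile-to-quintile = **medium**, rest = **low**.
4. **Development & validation.** Backward stepwise logistic development
   (Wald p < 0.05, interaction screening, education as a dummy block),
   Mann-Whitney AUC with DeLong CIs, sensitivity/specificity/PPV/NPV
   tables at 30/20/10% population cut-offs with Clopper-Pearson CIs,
   bootstrap internal validation, and external-cohort application.
5. **Synthetic cohorts.** Seeded generators matching the development
   (multi-ethnic, deprived-area UK birth cohort) and external (almost
   entirely White, leaner mothers) sample summaries, in a fast
   model-based mode and a raw-measurement growth mode, so the whole
   pipeline is testable without access to the original cohort data.

National growth references (e.g. UK90) are licensed tables and are not
redistributed; a smooth synthetic reference with infant-plausible
magnitudes (`growthrisk.synthetic_reference`) stands in for testing and
examples.

## Worked example

```python
import datetime as dt
import growthrisk as gr

refs = gr.synthetic_reference(seed=0)
config = gr.default_model_config()

result = gr.assess(
    sex="f", dob=dt.date(2023, 1, 10), assessment_date=dt.date(2023, 7, 20),
    birth_weight="3.2kg", current_weight="7.9kg",
    maternal_height="165cm", maternal_weight="70kg",
    refs=refs, conditional_model=config.conditional_model)
```

prints (via `examples/02_score_an_infant.py`):

```
equation used:    eq1 (with_maternal_bmi)
birthweight z:    -0.21
current weight z: +0.15
conditional gain: +0.39
risk probability: 0.055
risk band:        low
```

The infant is ~6.3 months old, so the first equation applies; maternal
height and weight were supplied, so the maternal-BMI variant is used.  Her
birthweight sits 0.21 SD below the reference median, her current weight
0.15 SD above, and her growth since birth is 0.39 SD faster than expected
for a baby starting at that size.  The resulting probability, 0.055, falls
below the medium-risk threshold for that equation, hence a low-risk band.

The same is available from a shell:

```bash
growthrisk reference --out ref.csv
growthrisk score --ref ref.csv --sex f --dob 2023-01-10 --date 2023-07-20 \
    --birthweight 3.2kg --weight 7.9kg
growthrisk simulate --preset bib-eq3 --n 10000 --seed 7 --out cohort.csv
growthrisk develop --cohort cohort.csv --out model.json
growthrisk diagnose --cohort cohort.csv --equation eq3
```

See `examples/` for short narrative scripts covering z-scoring, scoring,
cohort simulation, and equation development/validation.

## Layout

```
src/growthrisk/
  reference.py    LMS references, z-scores, centiles, unit parsing
  conditional.py  conditional gain and the composite outcome rule
  equations.py    published equations, window selection, scoring, banding
  develop.py      cohort records, ML logistic fitting, backward stepwise
  validate.py     AUC/DeLong, cut-off diagnostics, bootstrap, external
  simulate.py     seeded synthetic cohorts (model and growth modes)
  io.py           cohort CSV and model-config JSON/YAML
  cli.py          the `growthrisk` command
```
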