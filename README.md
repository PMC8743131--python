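# mrpipe

Two-sample and multivariable Mendelian randomization (MR) from GWAS
summary statistics, built for analyses of the kind that ask whether
genetic liability to a neurodevelopmental condition (ADHD, autism)
causally affects educational attainment — and vice versa — and how much
of any effect is independent of cognitive ability.

MR uses genetic variants as instrumental variables: a variant robustly
associated with an exposure, unconfounded, and affecting the outcome only
through that exposure identifies the exposure's causal effect. In the
two-sample setting the variant–exposure coefficients (β̂ₓⱼ, σₓⱼ) and
variant–outcome coefficients (β̂ᵧⱼ, σᵧⱼ) come from separate GWAS of
independent samples. `mrpipe` implements the full desk-scale workflow:

- **Instrument selection** — p-value thresholding (default 5×10⁻⁸),
  greedy LD clumping (r² < 0.01 within a 10 000 kb window) against a
  local LD table, and best-proxy substitution (r² > 0.9) for instruments
  missing from the outcome GWAS.
- **Harmonization** — aligning every trait's effects to a shared effect
  allele, resolving swapped labels and complementary-strand reporting,
  and excluding palindromic (A/T, C/G) variants unless allele frequencies
  can orient them.
- **Univariable estimators** — inverse-variance weighted (IVW)
  regression, β̂ = Σwⱼβ̂ₓⱼβ̂ᵧⱼ / Σwⱼβ̂ₓⱼ² with wⱼ = 1/σᵧⱼ², under fixed or
  multiplicative random-effects variance; MR-Egger with its
  directional-pleiotropy intercept test; SIMEX-adjusted Egger; weighted
  median; weighted mode; MR-RAPS (robust adjusted profile score) for weak
  instruments; per-SNP F statistics; Steiger directionality filtering.
- **Multivariable MR** — direct effects of two or more exposures by joint
  weighted regression, the exposure-uncertainty-weighted heterogeneity
  statistic Q_A, per-exposure conditional F statistics, and a
  weak-instrument-robust estimator minimizing Q_A with non-parametric
  bootstrap confidence intervals.
- **Effect scaling** — log-odds-scale exposure coefficients re-expressed
  per doubling of liability (×ln 2) and SD-unit outcomes converted to
  months/days of education (×4.2 years per SD); odds ratios with
  log-symmetric confidence intervals for binary outcomes.
- **Synthetic data** — a seeded generator of summary statistics with
  known causal structure (configurable pleiotropy regimes, sample sizes,
  LD blocks, palindromic fraction), so every stage is testable offline.

## Worked example

A study-shaped synthetic dataset (11 ADHD-like instruments with per-SNP F
in 30–51, a 212-instrument cognitive-ability-like second exposure, an
educational-attainment-like outcome; true effect −0.103 SD per unit
log-odds) run through the full pipeline:

```python
import mrpipe as m

bundle = m.study_shaped_fixture("adhd_to_ea", seed=0)
paths = bundle.write("example_data")
plan = m.AnalysisPlan(
    exposure=paths["exposure"], outcome=paths["outcome"], ld=paths["ld"],
    second_exposure=paths["second_exposure"], p_threshold=bundle.p_threshold,
    steiger=True, exposure_binary=True, n_exposure=55_000, n_outcome=766_000,
    outcome_sd_years=4.2, time_unit="months", boot_reps=1000, seed=1)
report = m.run_plan(plan, outdir="example_report")
print(report["results"])
```

prints (columns abridged):

```
 method  n_snps    beta     se  ci_low  ci_high  pvalue
    ivw      11 -0.0929 0.0125 -0.1174  -0.0685  0.0000
  egger      11  0.0921 0.1539 -0.2561   0.4403  0.5645
wmedian      11 -0.0933 0.0178 -0.1282  -0.0584  0.0000
  wmode      11 -0.0700 0.0265 -0.1220  -0.0180  0.0083
   raps      11 -0.0938 0.0102 -0.1138  -0.0738  0.0000
```

IVW estimates −0.093 SD of education per unit log-odds of liability
(truth −0.103 inside every robust estimator's CI; Egger is imprecise with
11 instruments, as expected). The scaled table re-expresses each row per
doubling of liability:

```
 method                          unit  value_rounded  ci_low_rounded  ci_high_rounded
    ivw months_per_liability_doubling           -3.2            -4.1             -2.4
```

i.e. a doubling of genetic liability costs about 3 months of education,
and the multivariable table separates the direct effect from the
cognitive-ability path:

```
exposure_id  direct_beta     se  ci_low  ci_high  conditional_F
       adhd      -0.0849 0.0104 -0.1052  -0.0646         3.0086
  cognitive       0.2972 0.0035  0.2903   0.3040       132.6545
```

The same analysis is available from the shell:

```sh
mrpipe run --config plan.yaml --out report/
mrpipe convert --beta -0.103 --se 0.023 --unit months   # -3.6 months/doubling
```

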