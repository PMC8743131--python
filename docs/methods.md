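# Methods

This note documents the statistical models implemented in `mrpipe`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter for
reproducing its output.

## Model and assumptions

Two-sample MR treats each genetic variant j as an instrumental variable.
With true variant–exposure effects γⱼ and a linear causal effect θ, the
variant–outcome effect is Γⱼ = θγⱼ + αⱼ, where αⱼ is a direct
(pleiotropic) path that the core IVW model assumes to be zero. The
observed summary coefficients are β̂ₓⱼ ~ N(γⱼ, σₓⱼ²) and
β̂ᵧⱼ ~ N(Γⱼ, σᵧⱼ²), independent across samples (two-sample design, no
overlap) and across variants (instruments are LD-clumped to near
independence). Binary traits analysed by logistic-regression GWAS carry
log-odds-scale coefficients; their MR estimates are interpreted per unit
log-odds of liability and rescaled as described below.

Each sensitivity estimator relaxes one assumption:

- **MR-Egger** allows directional pleiotropy with mean ≠ 0 provided the
  InSIDE condition holds (αⱼ independent of γⱼ); its intercept estimates
  the mean pleiotropic effect and its slope the adjusted causal effect.
  Identifiability requires a sign convention: rows are flipped so all
  exposure betas are non-negative before the fit.
- **SIMEX-adjusted Egger** corrects the Egger slope for regression
  dilution caused by noise in β̂ₓ: noise of variance λσₓⱼ² is added over
  a λ grid, the mean slope is fit as a quadratic in λ, and the fit is
  extrapolated to λ = −1 (the error-free limit). Row orientation is fixed
  from the observed betas before noise is added; per-replicate
  re-orientation would make the estimand discontinuous. The SE is a
  delete-one jackknife over replicates; when the exposure SEs are all
  (numerically) zero the jackknife collapses and the plain Egger SE is
  reported instead.
- **Weighted median / weighted mode** are consistent when, respectively,
  at least half the weight, or the largest weight cluster, comes from
  valid instruments. Ratio estimates β̂ᵧⱼ/β̂ₓⱼ are weighted by
  β̂ₓⱼ²/σᵧⱼ² (the inverse first-order ratio variance). The mode uses a
  normal kernel with the modified Silverman bandwidth
  0.9·min(sd, MAD/0.6745)·n^(−1/5) times a user factor. Both take their
  SEs from a parametric bootstrap (default 1000 resamples, seed
  required).
- **MR-RAPS** profiles out γⱼ, giving standardized residuals
  tⱼ(θ) = (β̂ᵧⱼ − θβ̂ₓⱼ)/√(σᵧⱼ² + θ²σₓⱼ² + τ²). The estimate minimizes
  Σρ(tⱼ) — whose gradient is exactly the profile-score estimating
  equation — with ρ quadratic (l2) or Huber (tuning 1.345, the default
  together with the overdispersion parameter τ², which solves
  Σ(ψ(tⱼ)tⱼ − δ)/sⱼ² = 0 with δ = E[ψ(Z)Z] under Z ~ N(0,1)). The loss
  is minimized locally around the fixed-effect IVW start with expanding
  bounds; the raw score equation is *not* root-found directly because it
  decays to zero in both tails and develops spurious far-away roots under
  weak instruments. SEs use the sandwich formula. θ and τ² are alternated
  to tolerances of 1e-8 (relative, θ) and 1e-10 (τ²).
- **Steiger filtering** drops variants that explain more variance in the
  outcome than in the exposure. Variance explained is r² = t²/(t²+n−2)
  for continuous traits; for binary traits the default observed-scale
  approximation is r = z/√n, with the t-statistic formula applied to the
  log-odds regression available behind `binary_r2="t_statistic"` (the
  liability-scale conversion is not identified from summary data alone,
  so both observed-scale options are exposed and the default is logged in
  every report). The per-variant Steiger test is the Fisher-z comparison
  of the two implied correlations.

**Multivariable MR** regresses β̂ᵧ on the K exposure-beta columns jointly
(no intercept, weights 1/σᵧⱼ²) to estimate direct effects. Heterogeneity
uses Q_A(θ) = Σ wⱼ(θ)(β̂ᵧⱼ − Σₖθₖβ̂ₓₖⱼ)² with
wⱼ(θ) = 1/(σᵧⱼ² + Σₖθₖ²σₓₖⱼ²), df = n − K; cross-exposure covariances of
the estimated effects are taken as zero (non-overlapping exposure GWAS),
since they are not recoverable from summary data. Conditional instrument
strength for exposure k regresses its betas on the other exposures'
betas with the same uncertainty-propagating weights — the auxiliary
coefficients are estimated by iteratively reweighted least squares
(direct minimization of the auxiliary Q is degenerate: it plateaus as the
coefficients grow because the weights vanish) — and reports
F = Q_x/(n − K + 1). The weak-instrument-robust estimator minimizes
Q_A(θ) (Nelder-Mead from the IVW solution with ±20% restarts, tolerance
1e-10) with 2.5/97.5 percentile confidence intervals from a
non-parametric bootstrap over instruments (default 1000 resamples), plus
a per-exposure flag recording whether the robust and IVW intervals
overlap.

## Instrument selection and harmonization

Selection keeps p ≤ 5×10⁻⁸ by default (a relaxed threshold such as
5×10⁻⁷ is a plan parameter, used when an exposure yields too few
genome-wide hits). Clumping is greedy in ascending p-value (ties broken
by variant ID for determinism): a variant is accepted iff r² < 0.01
against every accepted variant on the same chromosome within 10 000 kb.
LD comes from a local three-column table; pairs absent from it are
treated as unlinked and logged, matching common clumping-tool behaviour.
Instruments missing from the outcome GWAS are replaced by their
strongest LD partner with r² > 0.9 that is present in both files (the
whole record is swapped, so exposure and outcome stay aligned).

Harmonization fixes the first exposure's effect allele as the reference,
then aligns additional exposures and the outcome: swapped labels negate
the beta and mirror the frequency; complementary-strand pairs are mapped
first. Palindromic variants are excluded by default (the conservative
rule when frequencies are unavailable, as in the ADHD and ASD GWAS
releases); with `eaf_available` they are rescued by minor-allele matching
when both frequencies fall outside 0.5 ± 0.08 — the window default makes
0.42–0.58 always ambiguous, a conventional choice. The package restricts
to biallelic SNPs; indels and multi-allelics are dropped at read time and
counted in the log.

## Effect scaling

For a rare binary exposure the odds approximate the probability, so an
MR coefficient per unit log-odds times ln 2 gives the effect per
*doubling* of liability. SD-unit education outcomes are converted to time
with 4.2 years per SD, 12 months or 365 days per year — 365 (not 365.25)
is required to reproduce day-scale figures from month-scale ones exactly.
Reporting rounds to one decimal for months, integers for days, two
decimals for odds ratios; full precision is retained internally.

## Synthetic data

`simulate_pair`/`simulate_mvmr` draw true exposure effects from
N(0, 0.02²) — truncated so every variant passes the significance
threshold when instrument-grade effects are requested — and set
β̂ᵧ = θβ̂ₓ(true) + α + noise. Standard errors follow
1/√(2n·maf(1−maf)) with maf ~ U(0.05, 0.5) when frequencies are
requested and maf = 0.3 otherwise; defaults n_exp = 50 000 (an
ADHD-scale case-control GWAS) and n_out = 300 000 (a large continuous
trait GWAS). Pleiotropy regimes: `balanced` (mean-zero α), `directional`
(α sharing a sign per exposure-increasing allele — the orientation that
makes "directional" meaningful after harmonization), and
`inside_violating` (α correlated with γ). LD is emitted as exchangeable
within-block r², zero across blocks — enough structure for clumping and
proxy logic to have real work, without simulating genome-wide LD maps.
The generator does **not** emulate individual-level genotypes, sample
overlap, population stratification, or dynastic/assortative-mating
structure, so passing tests speak to estimator correctness under the
stated model, not to robustness against those real-data complications.

`study_shaped_fixture` emits bundles shaped like four reference
analyses — 11, 10, or 481 primary instruments with per-SNP F in the
reported ranges (30–51, 26–36, 30–240), a 212-instrument
cognitive-ability-like second exposure, one r² = 0.95 satellite per lead
(clumping fodder and proxy candidate), and non-significant filler. All
numbers in these bundles are synthetic; only the shapes follow the study
design.

## Experiment sizes

The acceptance experiments use desk-scale sizes chosen once: IVW coverage
over 1000 repetitions of 50 valid instruments from a 200 000-sample
exposure GWAS (strong instruments, so attenuation from exposure-beta
noise is negligible against the sampling SE); multivariable recovery of
(0.3, −0.2) over 500 repetitions of 200 instruments at exposure GWAS size
500 000; weak-instrument comparisons at mean F ≈ 5, arranged by drawing
untruncated effects with SD twice the exposure-beta SE (E[F] = 1 + σ²/se²
= 5). The test suite runs the same experiments at the same sizes; the
acceptance script uses 100–500 repetitions per experiment.

## Known limitations

- Conditional F statistics assume zero covariance between the exposures'
  estimated effects; with overlapping exposure GWAS samples they will be
  optimistic.
- The Steiger binary-trait r² is an observed-scale approximation; no
  liability-threshold prevalence model is implemented.
- MR-PRESSO-style outlier search, contamination-mixture estimators and
  colocalization are out of scope, as is any remote LD or GWAS service.
- The doubling-of-liability interpretation assumes the exposure is rare
  enough that odds ≈ probability; no correction is applied when it is
  not.
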