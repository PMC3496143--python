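# Methods

## Relative-risk model

The model is multiplicative over four components: Gail-type clinical
factors, percent mammographic density (PD) jointly with BMI, and a
polygenic profile of 18 (or the earlier subset of 7) breast-cancer
susceptibility loci.  Effect sizes are taken from published sources
and shipped as a packaged TSV (`mammorisk/data/effect_sizes_table1.tsv`):

* SNPs: per-allele odds ratios, coded so the low-risk homozygote is
  the baseline (`recode_to_risk_allele` inverts protective coding:
  OR < 1 becomes 1/OR with dosage 2 − d).  Loci are treated as
  independent and combined as Π ORᵢ^{dᵢ} (no linkage disequilibrium or
  interaction modelling).  Where several source studies report a
  locus, `pool_odds_ratios` provides the fixed-effect inverse-variance
  pooled estimate on the log-odds scale, with per-study variances
  recovered from 95% CI widths.
* PD: six categories (exactly 0%, (0,10), [10,25), [25,50), [50,75),
  [75,100]) with relative risks 1.00 / 1.27 / 2.00 / 2.98 / 3.70 /
  5.86.  BMI: five categories cut at 21.79 / 23.30 / 25.02 / 27.64
  kg/m² with risks 1.00 / 1.16 / 1.13 / 1.28 / 1.67.  All interval
  boundaries package-wide are lower-inclusive half-open; the published
  category labels overlap at the boundaries, so this is a package
  convention chosen for testability.
* Clinical: age at menarche (OR 1.10 per level) and age at first live
  birth (OR 1.24 per level) as log-linear trends over three ordinal
  levels, benign breast disease (OR 1.65) and first-degree family
  history (OR 2.07) as binary factors.  The published table prints a
  single OR per reproductive factor without category definitions; the
  per-level trend over three levels is the simplest consistent
  reading and is a documented interpretation, not a published fact.
  The two binary effects are re-estimable from data via
  `estimate_proxy_effects`, a logistic fit with the combined
  menarche/first-birth log relative risk entered as a fixed offset.

The "7-SNP" subset is taken to be the seven first-generation GWAS loci
present in the table (rs2981582, rs3803662, rs889312, rs13281615,
rs3817198, rs1045485, rs13387042).  Risk-allele frequencies are not
part of the published effect table; the packaged values are plausible
European-ancestry figures of the right order and are used only for
Hardy–Weinberg normalisation and synthetic genotype generation — they
do not affect any subject's risk ranking.

### Normalisation

Each component is divided by its population mean so the
population-average relative risk is 1: the Hardy–Weinberg mean
Π (p²OR² + 2p(1−p)OR + (1−p)²) for the SNPs, and expectations over a
configured `ReferenceDistribution` otherwise.  PD and BMI are
normalised jointly (their reference distribution is the
Gaussian-copula coupling of the category marginals with correlation
−0.40), since the two are negatively dependent.  The reference
defaults are exactly the synthetic generator's defaults, so scoring a
generated population returns mean relative risk 1.  This convention
makes the attributable-risk conversion exact and trivial: with E[r] = 1
the Bruzzi AR is 0 and composite incidence is already the baseline
hazard.  Non-normalised workflows are supported
(`population_attributable_risk(..., normalized=False)`, per-band AR in
`convert_to_baseline`).

Missing SNP dosages contribute a factor 1 on the normalised scale
(population-mean imputation), so partial genotype profiles remain
scorable and unbiased on average.

## Absolute risk

With piecewise-constant hazards the risk integral is analytic: on each
sub-interval of length Δ with total hazard λ = h₁r + h₂, the
contribution is S⁻·(h₁r/λ)·(1 − e^{−λΔ}), accumulated left to right
with S⁻ the joint survival since the start age.  The production path
is this closed form; an adaptive-quadrature oracle of the integrand is
kept in the test suite and agreement to 1e-8 relative error is part of
the acceptance checks.  Start ages are continuous (no rounding to band
starts); λ = 0 sub-intervals contribute 0.  `absolute_risk_vector`
vectorises over subjects by grouping on distinct start ages, which
makes 100,000-woman screening cohorts cheap.

## Evaluation statistics

* AUC: Mann–Whitney estimator with ties counted ½; variance and the
  paired difference test via DeLong structural components (midrank
  formulation); Wald 95% CIs clipped to [0,1].
* Reclassification: categories low (0,ε₁], intermediate (ε₁,ε₂], high
  (ε₂,1); a risk exactly at a cutoff goes to the lower category.  The
  total-sample table is the element-wise sum of the case and control
  tables.  Reported percentages are rounded half-up to integers, as in
  published tables.
* NRI: net up-moves for cases minus net up-moves for controls; Z from
  the Pencina asymptotic variance including the squared-net-move
  correction.  From the packaged published counts this yields
  Z = 5.67; the originally printed Z differs slightly and cannot be
  reproduced from the counts under either common variance variant, so
  only the point estimate is treated as exact.
* IDI: difference in mean risk separation, Z from the two groups'
  paired-difference standard errors.
* Hosmer–Lemeshow: deciles of predicted risk (ties kept together,
  empty/duplicate bins merged), statistic Σ(O−E)²/(E(1−E/n)) on
  g − 2 df.  For case-control data a location recalibration is applied
  first: an intercept-only logistic fit with logit(risk) as offset,
  whose intercept equals the log case/control sampling-fraction ratio;
  risks are shifted by it before grouping.  Brier scores are reported
  both raw and (via the recalibrated risks) after location adjustment.
* Case-capture/predictiveness curves: piecewise-linear in the
  population fraction q, with tied risks averaged over the tied block;
  weights are either observed labels or each woman's own risk
  (expected cases).

## Screening analysis

`build_cohort` draws ages 40–75 from configurable weights (uniform by
default; the emulated national age distribution is a user input) and
assigns each woman the full profile of a randomly chosen control from
her 5-year age band.  Women under 50 use the 50–54 band — the study
population is postmenopausal, so younger women are assumed to share
the age-50 risk-factor distribution — and women beyond the oldest
study band (70–74) use that band.  Genotypes travel jointly with the
non-genetic factors by default; an independent Hardy–Weinberg mode
exists.

10-year absolute risks are computed per model; the hazard table must
cover [40, 85) so 75-year-olds get a full horizon.  A strategy's
eligibility is the fraction with risk strictly above the cutoff;
expected-case capture weights each woman by her absolute risk under a
common reference model (`case_model`), so strategies are compared on
the same expected-case distribution.  `match_resources` inverts the
empirical risk distribution to hit a target eligibility; with
resampled profiles risks are heavily tied, so the cutoff is chosen
among attainable tie-block boundaries (exact to one member for
distinct risks).  The age-only comparator admits whole ages in
descending order of age-specific risk with fractional inclusion of the
marginal age.  `variance_sensitivity` rescales under-50 log relative
risks about their mean so their variance grows by a chosen factor
(default question: +10%) and re-evaluates each strategy at fixed
cutoffs.

Capture is analytic (variance-free); `sampled_capture` draws Bernoulli
case labels instead and is used in tests to confirm the two agree
within binomial error.

## Synthetic data

The generator emulates a postmenopausal case-control study, ages
50–74, defaults 1,017 cases / 856 controls (the complete-data subset
size of the emulated study):

* genotypes: independent loci, Hardy–Weinberg at the packaged allele
  frequencies;
* PD and BMI: Gaussian copula with latent correlation −0.40
  discretised to the published category grids, uniform within
  category (PD category "0" is an atom at exactly 0%; open-ended top
  categories are capped at 100% PD and 42 kg/m²); marginals default
  to (0.08, 0.12, 0.25, 0.30, 0.18, 0.07) for PD and equal fifths for
  BMI (the published BMI cuts are cohort quintiles);
* clinical factors: independent draws, menarche levels (0.30, 0.45,
  0.25), first-birth levels (0.35, 0.40, 0.25), benign breast disease
  prevalence 0.10, family history prevalence 0.12.  These marginals
  are plausible placeholders — the emulated study does not publish
  them — and are the package's declared reference distribution;
* case status: rejection sampling with P(case|profile) =
  c·r/(1 + c·r), i.e. disease odds proportional to the full-model
  relative risk, with baseline odds c set by a population disease
  probability of 0.03 over the ascertainment window.  Odds
  proportionality (rather than probability proportionality) is chosen
  deliberately: the published effects are odds ratios, and under this
  scheme logistic refits on generated data are consistent for them,
  which the recovery tests exploit.  Configs with population rate
  ≥ 0.5 are rejected as infeasible (baseline odds ≥ 1);
* controls: drawn from the same population with the complementary
  probability, then ages re-drawn from the realised case age
  distribution (frequency matching).

Hazard tables are generated, not shipped: composite incidence rising
linearly from ~120 per 100,000 at ages 40–44 (slope 9 per 100,000 per
year of mid-age) and competing mortality rising exponentially from
~180 per 100,000 (log-slope 0.085/year), spanning [40, 85) — Western
female orders of magnitude.  Optional seeded log-normal jitter,
monotonicity enforcement and a zero-mortality flag support testing.

### What the generator does and does not emulate

Because case status is generated from the full model itself, the full
model is correctly specified on synthetic data: discrimination (AUC
≈ 0.67 for five-year risks) and the screening advantage of the full
model are upper bounds relative to what the same pipeline yields on
real data, where effects are estimated with error and the model is
approximate.  The generator also omits linkage disequilibrium,
age-dependent effect sizes, measurement error in PD, and any
dependence of risk factors on age within 50–74.  Passing tests
therefore demonstrate internal correctness of the machinery and
consistency of the estimators, not real-world predictive performance.

## Numerical choices and degenerate inputs

* Proportion vectors must sum to 1 within 1e-9 (table inputs are exact
  fractions).
* Zero-width CIs, non-positive rates/risks/odds ratios, out-of-range
  PD/BMI, single-class label vectors and mismatched lengths raise
  `ValueError` with the offending item named; unstable logistic fits
  (complete separation) raise `EstimationError` rather than returning
  extreme coefficients.
* All stochastic operations take explicit seeds (numpy `default_rng`)
  and are bit-reproducible.
* Reported table percentages round half-up; internal statistics are
  never rounded.
* Test problem sizes (e.g. 100 random schedules for the quadrature
  comparison, 200 replicates for calibration and capture checks,
  20 × 100,000-woman screening replicates, n = 20,000 recovery
  cohorts) are the package's standard validation sizes, chosen to make
  Monte-Carlo error comfortably smaller than the tested effects.

## Known limitations

* Lifetime risks beyond the hazard table's support are not
  extrapolated.
* Time-to-event (censoring-aware) AUC/NRI variants are out of scope.
* The screening comparison is analytic and static: no screening
  sensitivity, sojourn time, over-diagnosis or mortality benefit;
  risk scores do not evolve within a woman's follow-up.
* Family-history modelling is a single binary indicator; allele
  frequencies and clinical-factor marginals are documented
  assumptions, not published values.
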