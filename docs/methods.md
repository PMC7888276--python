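# Methods

## Design

`mrcox` implements a one-sample Mendelian-randomization (MR) analysis with
a censored survival outcome. The estimand throughout is θ, the log hazard
ratio of incident disease per unit of the exposure (natural-log CRP in
mg/L, or the log-odds of chronic inflammation defined as CRP > 3.0 mg/L).
The pipeline has five stages, each an importable module:

1. **simulate** — generate a synthetic cohort with the statistical
   structure the analysis assumes (below);
2. **instruments** — curate the variant panel: genotype QC, LD pruning,
   cross-study merging, pleiotropic-variant exclusion, effect-allele
   orientation, allele scoring;
3. **snp_outcome** — per-variant Cox regressions per sub-study with two
   adjustment stages, Schoenfeld proportional-hazards diagnostics, and
   fixed-effect meta-analysis;
4. **estimators** — Wald ratios and the pooled summary-statistic
   estimators (IVW, WM, PWM, MR-Egger, Cochran's Q);
5. **gxe / pipeline** — the gene–environment corrected estimate and the
   stratified/subtype orchestration with Benjamini–Hochberg correction.

## The synthetic cohort

The simulator emulates a postmenopausal cohort of n = 10,179 women in five
sub-studies followed for breast cancer incidence. Its defaults are the
conditions the package is validated under; every one is overridable in
`SimulationConfig`.

**Genetics and exposure.** 61 independent variants with allele frequencies
uniform on (0.05, 0.5). Effect magnitudes are drawn as 0.5 + |N(0,1)| and
rescaled so the expected exposure variance explained,
Σ 2p<sub>j</sub>(1−p<sub>j</sub>)β<sub>j</sub>² / Var(ln CRP), equals the
6% target; the offset keeps every effect bounded away from zero, as it is
for any genome-wide-significant instrument panel. Genotypes are
Hardy–Weinberg binomial draws, independent across variants (an optional
Gaussian-copula block generator exists solely to exercise LD pruning; the
latent within-block correlation attenuates on the dosage scale).
ln CRP = 0.7 + Σβ<sub>j</sub>(g<sub>j</sub> − 2p<sub>j</sub>) + ε with ε
scaled so total variance is 1.0 — a median CRP around 2 mg/L, with about a
quarter of women above the 3.0 mg/L inflammation threshold.

**Outcomes.** Event times are exponential with hazard
λ₀·exp(θ·(ln CRP − 0.7)); θ defaults to 0.2 and can be multiplied within
named lifestyle strata (`modifier_effects`) or split by ER/PR subtype via
competing cause-specific hazards (`subtype_theta`). Observed time is the
minimum of the event time, administrative censoring uniform on
[16, 21] years (a 5-year enrollment window before a common study end), and
exponential loss to follow-up. The three free rates were calibrated once
by stochastic root-finding against the cohort descriptors the simulator
emulates — 5% cumulative incidence and a 16-year mean follow-up — giving
λ₀ = 3.06×10⁻³ events/person-year at mean exposure and a dropout hazard of
1.28×10⁻² /year. Subtype labels (ER/PR 80% positive, HER2 15% positive)
are drawn for events only and are independent of CRP unless
`subtype_theta` says otherwise.

**Covariates.** Lifestyle covariates are drawn from documented marginal
defaults chosen to be plausible for the eligible population (age uniform
50–79; BMI log-normal with mean 28 kg/m²; WHR normal 0.84 ± 0.07; MET
exponential mean 12 h/wk; hormone-use durations zero-inflated exponential,
etc. — see `simulate_phenotypes`). Only marginal realism is intended: the
covariates are independent of genotype and of each other, so passing tests
demonstrate the machinery's correctness under the model's assumptions, not
robustness to real-world confounding, covariate correlation, population
structure, or genotyping artefacts. Principal components are pure noise
stand-ins taken as given covariates.

**Two-sample summary statistics.** `simulate_summary_stats` emits
γ̂<sub>j</sub> ~ N(β<sub>j</sub>, 0.0035) and Γ̂<sub>j</sub> ~
N(θβ<sub>j</sub> + δ·1[j invalid], 0.067); the SEs correspond roughly to an
exposure GWAS of ~2×10⁵ samples and an outcome cohort with ~540 events.
The invalid set is filled greedily in random order until it holds the
configured share of total inverse-variance weight, and δ
(`pleiotropy_shift`) is a directional (all-positive) pleiotropic effect —
the hardest case for IVW and the regime where the weighted median's 50%
breakdown property matters.

## Estimation choices

**Cox fits.** lifelines' `CoxPHFitter` (Efron tie handling; ties have
probability zero in the continuous-time simulator anyway). Complete-case
rows per model with dropped counts logged; separation or non-convergence
yields an infinite-SE sentinel that downstream pooling excludes. Models
are fit separately per sub-study and pooled by fixed-effect
inverse-variance meta-analysis; time origin is enrollment, scale years, no
left truncation. The proportional-hazards diagnostic is the Pearson
correlation ρ between the scaled Schoenfeld residuals of the dosage term
and event-time rank.

**Wald ratios.** First-order SE (se<sub>Γ</sub>/|γ̂|) by default; the
second-order form adds the exposure-uncertainty term and accepts an
optional γ̂–Γ̂ covariance for one-sample overlap (default 0 — the overlap
correction is a documented limitation, not an automatic adjustment).

**Weighted median and bootstrap.** The WM interpolates the ordered ratios
at normalized cumulative weight 0.5; the PWM first multiplies weights by
min(1, 20·p<sub>j</sub>) with p<sub>j</sub> the χ²₁ upper tail of the
instrument's Q contribution, and re-penalizes inside every bootstrap draw.
Standard errors come from a seeded parametric bootstrap (default 1000
draws). The bootstrap population is centered at the point estimate
(`boot_center="consensus"`): drawing instead around each observed ratio —
the scheme common in two-sample MR software, available as
`boot_center="observed"` — over-disperses the bootstrap population because
the observed ratios already contain their sampling noise, and measured
against Monte-Carlo truth it inflates the SE by ~20% and pushes interval
coverage to ~98%. The consensus-centered draws reproduce nominal ~95%
coverage under instrument validity; under genuine heterogeneity they lean
on the homogeneity assumption and can be mildly anticonservative, which is
the usual trade-off.

**MR-Egger.** Weighted least squares with unscaled (fixed-effect)
covariance, so the intercept-constrained slope is algebraically identical
to IVW under the same weights. Exposure effects must be (or are, in the
pipeline) oriented non-negative so the intercept's direction is
interpretable.

**G×E.** Across-strata weighted regression of the score–outcome log
hazard ratio on the score–exposure slope (weights 1/se(Γ<sub>s</sub>)²),
normal-theory CIs; with two strata this is the exact two-point form. The
identifiability guard refuses constant score–exposure strength rather than
returning an arbitrary slope. The binary-scale instruments are never
pooled with log-continuous ones in any estimator run, and the genetic
score uses log-continuous instruments only.

**Score rescaling.** OLS of ln CRP on the raw score among unaffected
women; the fitted line b₀ + b₁·GS is applied to all individuals, a
positive affine map, so raw and rescaled scores correlate at exactly 1.

**Instrument strength.** F = (R²/(1−R²))·((n−k−1)/k). At R² = 0.06 and
n = 10,179 this gives ≈ 11 for k = 61 instruments and ≈ 108 for k = 6
(e.g., a handful of score terms); published headline values in this
literature are consistent with the latter convention. The function exposes
the formula and a weak-instrument flag at the conventional F < 10.

**Multiple testing.** Step-up Benjamini–Hochberg within each analysis
family — by default each (modifier, stage, method) group of strata,
mirroring per-figure adjustment; family composition is configurable.

**Subtypes.** Cause-specific censoring: events of other subtypes are
censored at diagnosis. Competing-risk subdistribution models are out of
scope.

## Numerical and edge-case conventions

- Hardy–Weinberg: 1-df χ² on rounded genotype counts, no continuity
  correction; monomorphic variants pass trivially. "LD < 0.3" is read as
  squared dosage correlation r² < 0.3, the conventional pruning statistic.
- LD pruning ranks by |γ̂/se| with lexicographic variant-id tie-break;
  constant-dosage variants (undefined correlation) are excluded with a
  warning.
- Cross-study duplicates keep the most recent publication, ties to the
  smaller SE; swapped-allele records are reconciled by sign/frequency
  flip, irreconcilable alleles raise a harmonization error.
- Missing dosages in the genetic score are mean-imputed at 2·EAF with a
  logged count.
- Strata below 10 events (configurable) are reported as skipped, not
  estimated. Duration strata use half-open [a, b) bins with exact zero as
  non-use.
- Every stochastic operation draws from `numpy` Generators keyed by
  (seed, stage), so a configuration reproduces its outputs byte for byte.

## Validation problem sizes

The test suite validates parameter recovery at sizes chosen to keep the
full run in minutes while leaving Monte-Carlo error well inside the
asserted tolerances: two-sample recovery uses 500 replicates of 60
instruments (bias tolerance 0.02 against a per-replicate sd ≈ 0.17–0.22);
the one-sample pipeline uses 100 replicates of n = 2,000 cohorts with 15
variants; the weighted-median breakdown sweep uses 300 replicates at each
of six invalid-weight fractions; simulator calibration is checked at the
full n = 10,179. `scripts/acceptance.py` averages the calibration
descriptors over 20 cohorts at full size.

## Known limitations

- No realistic LD maps, population structure, imputation error, or
  genotype missingness patterns; QC operations are validated on planted
  defects.
- The one-sample winner's-curse/overlap correction is exposed only as an
  optional covariance term in the second-order Wald SE.
- Cox non-collapsibility means per-allele log hazard ratios attenuate
  toward zero as event fractions grow; at the default 5% incidence the
  attenuation is negligible, but simulations run at inflated baseline
  hazards (some tests use ~12%) recover a slightly shrunken θ — tests
  assert coverage, not point equality, in those regimes.
- MR-PRESSO, mode-based estimators, multivariable MR and competing-risk
  subdistribution hazards are out of scope.
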