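# mrcox

One-sample Mendelian randomization (MR) with time-to-event outcomes, built
around the question of whether genetically predicted C-reactive protein
(CRP) — a marker of chronic low-grade inflammation — causally influences the
risk of incident invasive breast cancer in postmenopausal women.

The package is aimed at genetic epidemiologists who want to run (or stress-
test) a survival-outcome MR analysis end to end: curate genetic instruments
from GWAS summary statistics, estimate per-variant associations with a
censored outcome by Cox regression inside a multi-sub-study cohort, combine
them with instrument–exposure effects through estimators robust to partial
instrument invalidity, and probe effect modification by lifestyle strata and
tumour molecular subtype. Because the motivating cohort data (WHI dbGaP) are
access-restricted, the package ships a first-class synthetic-cohort
simulator with the same statistical structure, so every stage is testable at
desk scale.

## The model

Each genetic variant *j* carries an exposure effect γ<sub>j</sub> (change in
ln CRP mg/L — or log-odds of CRP > 3.0 mg/L — per effect allele) and an
outcome effect Γ<sub>j</sub>, the log hazard ratio per allele from a Cox
proportional-hazards model h(t) = h₀(t)·exp(Γ·g + covariates), fit per
sub-study under two adjustment stages (1: age + 10 genetic PCs; 2: + 15
lifestyle/demographic covariates) and pooled by fixed-effect meta-analysis.
The causal log hazard ratio per unit exposure is estimated from the
per-variant Wald ratios β̂<sub>j</sub> = Γ̂<sub>j</sub>/γ̂<sub>j</sub> with
weights w<sub>j</sub> = 1/se(β̂<sub>j</sub>)²:

- **IVW**: θ̂ = Σw<sub>j</sub>β̂<sub>j</sub> / Σw<sub>j</sub> (equivalently
  the weighted through-origin regression of Γ̂ on γ̂);
- **Weighted median (WM)**: the interpolated 50% point of the
  weight-ordered β̂<sub>j</sub>, consistent while valid instruments hold
  >50% of the weight;
- **Penalized weighted median (PWM)**: WM after down-weighting instruments
  with outlying Cochran-Q contributions (w<sub>j</sub>·min(1, 20·p<sub>j</sub>),
  p<sub>j</sub> from χ²₁);
- **MR-Egger**: weighted regression of Γ̂ on γ̂ *with* intercept; a nonzero
  intercept signals directional pleiotropy;
- **Cochran's Q**: Σw<sub>j</sub>(β̂<sub>j</sub> − θ̂<sub>IVW</sub>)² as a
  heterogeneity/pleiotropy diagnostic;
- **MR G×E**: across environment strata *s*, regress the genetic-score
  outcome association Γ<sub>s</sub> on the score–exposure association
  γ<sub>s</sub>; the slope is a pleiotropy-corrected causal estimate and the
  intercept the constant pleiotropic effect.

All results are reported as hazard ratios HR = exp(θ̂) with normal-theory
95% intervals, per unit log-CRP or log-odds of chronic inflammation.

## Worked example

```python
from mrcox import SimulationConfig, simulate_cohort, run_mr

cfg = SimulationConfig(n_individuals=4000, n_variants=20,
                       causal_effect_theta=0.3, n_substudies=2, seed=7)
cohort, genotypes, variants, truth = simulate_cohort(cfg)
print(f"cohort: n={len(cohort)}, events={int(cohort.event.sum())}, "
      f"mean follow-up={cohort.followup_years.mean():.1f} y")
results = run_mr(cohort, genotypes, variants, stage=1,
                 gammas_from_cohort=True, boot_reps=500, seed=7)
for r in results:
    print(f"{r.method:16s} HR {r.hr:5.2f} "
          f"(95% CI {r.hr_low:.2f}-{r.hr_high:.2f}) p={r.p:.3f}")
```

prints

```
cohort: n=4000, events=220, mean follow-up=16.0 y
IVW              HR  1.38 (95% CI 0.85-2.24) p=0.200
WM               HR  1.88 (95% CI 1.04-3.39) p=0.036
PWM              HR  1.89 (95% CI 1.03-3.49) p=0.040
Egger-slope      HR  2.39 (95% CI 0.73-7.84) p=0.150
Egger-intercept  HR  0.94 (95% CI 0.83-1.06) p=0.317
```

The simulated truth is a hazard ratio of exp(0.3) ≈ 1.35 per unit log-CRP;
every estimator's interval covers it, the median-based estimators run a
little high on this single draw, and the Egger intercept (its "HR" column is
exp of the intercept) shows no directional pleiotropy — as it should, since
none was simulated.

The same chain is scriptable from a shell:

```
mrcox simulate --seed 7 --out-dir run1
mrcox snp-outcome --cohort run1/cohort.csv --genotypes run1/genotypes.tsv \
    --stage 1 --out run1/snp_outcome.tsv
mrcox mr --instruments run1/instruments.tsv \
    --snp-outcome run1/snp_outcome.tsv --out run1/mr.tsv
```

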