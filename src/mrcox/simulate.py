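"""Synthetic postmenopausal-cohort simulator.

Generates individual-level cohorts and two-sample summary statistics with
the statistical structure the MR-survival analysis assumes, so every
downstream stage is testable without restricted data access:

* a panel of independent exposure-raising variants whose joint effect
  explains a configurable fraction (default ~6%) of log-CRP variance;
* Hardy-Weinberg genotypes, optionally with block LD;
* log-normal CRP built additively from dosages plus Gaussian noise, with
  chronic inflammation defined as CRP > 3.0 mg/L;
* lifestyle covariates (documented marginal defaults, overridable);
* proportional-hazards event times with administrative censoring plus a
  small loss-to-follow-up hazard, calibrated at default settings to
  ~5% cumulative incidence and a ~16-year mean follow-up at n = 10,179;
* hormone-receptor (ER/PR) and HER2 subtype labels on events, optionally
  with subtype-specific causal effects;
* two-sample per-variant summary statistics with a configurable share of
  instrument weight assigned directional pleiotropy.

Every operation derives its random stream from ``config.seed`` and a
fixed per-stage key, so an identical configuration reproduces every
output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InfeasibleCalibrationError
from .instruments import VariantRecord
from .strata import StratumSpec, assign_strata, default_strata

__all__ = [
    "SimulationConfig",
    "TrueParameters",
    "simulate_variants",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_outcomes",
    "simulate_cohort",
    "simulate_summary_stats",
    "write_dosage_vcf",
    "read_dosage_vcf",
    "write_manifest",
]

_PLEIOTROPY_POOL = ("BMI", "2-h glucose", "T2DM", "LDL")
_SOURCE_STUDIES = (("CRP-GWAS-A", 2011), ("CRP-GWAS-B", 2016), ("CRP-GWAS-C", 2018))


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Defaults are the study conditions the package is tested under: a
    cohort of 10,179 women carrying 61 independent CRP-raising variants
    that jointly explain ~6% of log-CRP variance, followed for a mean of
    ~16 years with ~5% cumulative incidence, recruited into 5 sub-studies.

    Outcome-model defaults were calibrated once against those targets:
    ``baseline_hazard`` = 3.06e-3 events/person-year at mean exposure,
    administrative censoring uniform on
    [``max_followup_years`` - ``enrollment_window_years``,
    ``max_followup_years``] (a 5-year enrollment window before a common
    study end ~21 years on), and an exponential loss-to-follow-up hazard
    ``dropout_rate`` = 1.28e-2 /year.

    ``causal_effect_theta`` is the true log hazard ratio per unit
    log-CRP (mg/L) — the estimand every MR estimator must recover.
    ``modifier_effects`` maps a stratifying covariate to per-stratum
    multiplicative modifications of theta, e.g.
    ``{"ep_years": {"<5": 0.2}}``.
    """

    n_individuals: int = 10_179
    n_variants: int = 61
    maf_range: tuple = (0.05, 0.5)
    target_r2: float = 0.06
    causal_effect_theta: float = 0.2
    baseline_hazard: float = 3.06e-3
    max_followup_years: float = 21.0
    enrollment_window_years: float = 5.0
    dropout_rate: float = 1.28e-2
    n_substudies: int = 5
    modifier_effects: dict = field(default_factory=dict)
    invalid_fraction: float = 0.0
    pleiotropy_shift: float = 0.0
    seed: int = 0
    # exposure scale: natural-log CRP in mg/L
    exposure_mean: float = 0.7
    exposure_sd: float = 1.0
    # subtype composition of incident cases
    erpr_pos_prob: float = 0.8
    her2_pos_prob: float = 0.15
    subtype_theta: dict | None = None  # {"erpr_positive": th, "erpr_negative": th}
    n_pleiotropy_tagged: int = 4
    # two-sample summary-statistic noise scales
    se_gamma: float = 0.0035
    se_big_gamma: float = 0.067

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("maf_range must lie within (0, 1)")
        if not 0 <= self.target_r2 < 1:
            raise ValueError("target_r2 must be in [0, 1)")
        if not 0 <= self.invalid_fraction <= 1:
            raise ValueError("invalid_fraction must be in [0, 1]")
        if self.n_substudies < 1:
            raise ValueError("n_substudies must be >= 1")
        if min(self.n_individuals, self.n_variants) <= 0:
            raise ValueError("counts must be positive")
        if self.baseline_hazard < 0:
            raise ValueError("baseline_hazard must be non-negative")

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-keyed generator: independent streams per pipeline stage."""
        return np.random.default_rng([int(self.seed), stage])


@dataclass
class TrueParameters:
    """Ground truth of one simulated dataset, for recovery tests."""

    theta: float
    per_variant_exposure_betas: np.ndarray
    invalid_variant_ids: frozenset
    realized_r2: float


def simulate_variants(config: SimulationConfig) -> tuple[list[VariantRecord], TrueParameters]:
    """Draw the instrument panel and its true exposure effects.

    Allele frequencies are uniform on ``maf_range``; raw normal effect
    sizes are rescaled so the expected exposure variance explained,
    sum_j 2 p_j (1-p_j) beta_j^2 / Var(log-CRP), equals ``target_r2``.
    Every record is returned already oriented to the CRP-raising allele
    (beta >= 0); source-study labels cycle through three named GWAS
    sources and a few variants carry pleiotropy tags.
    """
    rng = config.rng(1)
    J = config.n_variants
    mafs = rng.uniform(*config.maf_range, size=J)
    # offset half-normal magnitudes: GWAS-selected instruments clear a
    # significance threshold, so effects are bounded away from zero
    raw = (0.5 + np.abs(rng.normal(size=J))) * rng.choice([-1.0, 1.0], size=J)
    var_per_unit = 2 * mafs * (1 - mafs) * raw**2
    total_raw = float(var_per_unit.sum())
    if config.target_r2 > 0 and total_raw == 0:
        raise InfeasibleCalibrationError(
            "cannot reach positive target_r2: zero genetic variance at these settings"
        )
    if config.target_r2 == 0:
        betas = np.zeros(J)
    else:
        scale = np.sqrt(config.target_r2 * config.exposure_sd**2 / total_raw)
        betas = raw * scale
    # orient: CRP-raising allele is the effect allele
    flip = betas < 0
    betas = np.abs(betas)
    eafs = np.where(flip, 1 - mafs, mafs)

    ids = rng.choice(np.arange(10_000, 10_000_000), size=J, replace=False)
    chroms = rng.integers(1, 23, size=J)
    positions = rng.integers(1, 250_000_000, size=J)
    tagged = set(rng.choice(J, size=min(config.n_pleiotropy_tagged, J), replace=False).tolist())

    records = []
    for j in range(J):
        study, year = _SOURCE_STUDIES[j % len(_SOURCE_STUDIES)]
        tags = frozenset({_PLEIOTROPY_POOL[j % len(_PLEIOTROPY_POOL)]}) if j in tagged else frozenset()
        records.append(
            VariantRecord(
                variant_id=f"rs{ids[j]}",
                chrom=str(chroms[j]),
                pos=int(positions[j]),
                effect_allele="A" if not flip[j] else "G",
                other_allele="G" if not flip[j] else "A",
                eaf=float(eafs[j]),
                gamma_hat=float(betas[j]),
                se_gamma=config.se_gamma if config.se_gamma > 0 else 1e-6,
                exposure_scale="log-continuous",
                source_study=study,
                publication_year=year,
                pleiotropy_tags=tags,
            )
        )
    realized = float((2 * eafs * (1 - eafs) * betas**2).sum() / config.exposure_sd**2)
    true = TrueParameters(
        theta=config.causal_effect_theta,
        per_variant_exposure_betas=betas,
        invalid_variant_ids=frozenset(),
        realized_r2=realized,
    )
    return records, true


def simulate_genotypes(
    variants,
    n: int,
    seed=0,
    ld_block_size: int | None = None,
    ld_rho: float = 0.0,
) -> pd.DataFrame:
    """Hardy-Weinberg genotypes, independent across variants by default.

    ``variants`` is a list of :class:`VariantRecord` or a bare array of
    effect-allele frequencies.  With ``ld_block_size`` set, consecutive
    variants within a block share a latent Gaussian factor of weight
    ``ld_rho`` on each of the two allele draws, inducing positive
    dosage correlation within blocks (for exercising LD pruning only;
    no attempt at realistic human LD).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    if len(variants) == 0:
        raise ValueError("variants must be non-empty")
    if isinstance(variants[0], VariantRecord):
        freqs = np.array([v.eaf for v in variants])
        ids = [v.variant_id for v in variants]
    else:
        freqs = np.asarray(variants, float)
        ids = [f"v{j}" for j in range(len(freqs))]
    J = len(freqs)
    if ld_block_size is None or ld_rho == 0.0:
        dosages = rng.binomial(2, freqs, size=(n, J)).astype(float)
    else:
        # Gaussian-copula alleles: one shared factor per (block, haplotype)
        thresh = _norm_ppf(freqs)
        dosages = np.zeros((n, J))
        for h in range(2):
            n_blocks = int(np.ceil(J / ld_block_size))
            shared = rng.normal(size=(n, n_blocks))
            noise = rng.normal(size=(n, J))
            block_of = np.arange(J) // ld_block_size
            latent = np.sqrt(ld_rho) * shared[:, block_of] + np.sqrt(1 - ld_rho) * noise
            dosages += (latent < thresh).astype(float)
    return pd.DataFrame(dosages, columns=ids)


def _norm_ppf(q):
    from scipy.stats import norm

    return norm.ppf(q)


def simulate_phenotypes(
    genotypes: pd.DataFrame,
    true_params: TrueParameters,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Build log-CRP from dosages and attach lifestyle covariates.

    log-CRP_i = mean + sum_j beta_j (g_ij - 2 eaf_j) + e_i with the noise
    variance set so total variance equals ``exposure_sd**2`` and the
    genetic share equals the calibrated r-squared.  The binary chronic
    inflammation indicator is CRP > 3.0 mg/L.  Covariates are drawn from
    documented marginal default distributions (see docs/methods.md);
    only marginal realism is intended.
    """
    rng = config.rng(3)
    n, J = genotypes.shape
    betas = np.asarray(true_params.per_variant_exposure_betas, float)
    if betas.shape[0] != J:
        raise ValueError("genotype matrix not conformable with true parameters")
    dos = genotypes.to_numpy(float)
    genetic = (dos - dos.mean(axis=0)) @ betas
    noise_var = max(config.exposure_sd**2 - true_params.realized_r2 * config.exposure_sd**2, 0.0)
    log_crp = config.exposure_mean + genetic + rng.normal(0, np.sqrt(noise_var), size=n)

    cohort = pd.DataFrame(index=genotypes.index)
    cohort["individual_id"] = [f"I{i:06d}" for i in range(n)]
    cohort["substudy"] = np.array([f"S{k + 1}" for k in rng.integers(config.n_substudies, size=n)])
    cohort["age"] = rng.uniform(50, 79, size=n)
    for k in range(1, 11):
        cohort[f"pc{k}"] = rng.normal(size=n)
    # anthropometry: BMI log-normal around 28 kg/m2, WHR around 0.84
    sigma_bmi = 0.18
    cohort["bmi"] = rng.lognormal(np.log(28) - sigma_bmi**2 / 2, sigma_bmi, size=n)
    cohort["height_cm"] = rng.normal(162, 6, size=n)
    cohort["weight_kg"] = cohort["bmi"] * (cohort["height_cm"] / 100) ** 2
    cohort["hip_cm"] = rng.normal(104, 8, size=n)
    cohort["whr"] = np.clip(rng.normal(0.84, 0.07, size=n), 0.55, 1.2)
    cohort["waist_cm"] = cohort["whr"] * cohort["hip_cm"]
    cohort["met_hours_week"] = rng.exponential(12, size=n)
    cohort["sfa_pct_calories"] = np.clip(rng.normal(11, 3, size=n), 0, None)
    cohort["alcohol_g_day"] = np.where(rng.random(n) < 0.6, 0.0, rng.exponential(8, size=n))
    cohort["cigarettes_per_day"] = np.where(rng.random(n) < 0.9, 0.0, rng.gamma(2.0, 6.0, size=n))
    cohort["cesd_score"] = np.clip(rng.exponential(0.04, size=n), 0, 1)
    cohort["family_history"] = (rng.random(n) < 0.16).astype(int)
    cohort["age_menopause"] = np.clip(rng.normal(49, 4, size=n), 30, 60)
    cohort["education"] = rng.integers(1, 6, size=n)
    cohort["family_income"] = rng.integers(1, 9, size=n)
    # zero-inflated exogenous-hormone durations, capped at 25 years
    cohort["e_only_years"] = np.where(rng.random(n) < 0.65, 0.0, np.minimum(rng.exponential(5, size=n), 25))
    cohort["ep_years"] = np.where(rng.random(n) < 0.70, 0.0, np.minimum(rng.exponential(5, size=n), 25))
    cohort["oc_years"] = np.where(rng.random(n) < 0.60, 0.0, np.minimum(rng.exponential(4, size=n), 25))
    cohort["log_crp"] = log_crp
    cohort["crp_mgL"] = np.exp(log_crp)
    cohort["inflammation"] = (cohort["crp_mgL"] > 3.0).astype(int)
    return cohort


def _theta_per_individual(cohort: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    theta = np.full(len(cohort), config.causal_effect_theta, float)
    specs = {s.variable: s for s in default_strata()}
    for variable, mods in config.modifier_effects.items():
        spec = specs.get(variable)
        if spec is None:
            spec = StratumSpec(variable, "category", (), ("no", "yes"))
        labels = assign_strata(cohort, spec)
        for label, mult in mods.items():
            theta = np.where(labels.to_numpy() == label, theta * mult, theta)
    return theta


def simulate_outcomes(cohort: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Attach time-to-event, event indicator, and subtype labels.

    Event times are exponential given the linear predictor
    theta_i * (log-CRP_i - mean); theta_i is the configured causal effect
    modified multiplicatively within ``modifier_effects`` strata.
    Observed time is the minimum of the event time, an administrative
    censoring time uniform over the enrollment window, and an
    exponential loss-to-follow-up time.  ER/PR and HER2 labels are drawn
    for events only; with ``subtype_theta`` set, ER/PR-positive and
    -negative tumours arise from competing cause-specific hazards with
    their own log hazard ratios.
    """
    if config.baseline_hazard < 0:
        raise ValueError("baseline hazard must be non-negative")
    rng = config.rng(4)
    n = len(cohort)
    z = cohort["log_crp"].to_numpy() - config.exposure_mean
    theta_i = _theta_per_individual(cohort, config)

    if config.subtype_theta is None:
        lam = config.baseline_hazard * np.exp(theta_i * z)
        with np.errstate(divide="ignore"):
            t_event = rng.exponential(np.where(lam > 0, 1 / lam, np.inf))
        erpr_pos = rng.random(n) < config.erpr_pos_prob
    else:
        mult = theta_i / np.where(config.causal_effect_theta != 0, config.causal_effect_theta, 1.0)
        th_pos = config.subtype_theta.get("erpr_positive", config.causal_effect_theta) * mult
        th_neg = config.subtype_theta.get("erpr_negative", config.causal_effect_theta) * mult
        lam_pos = config.baseline_hazard * config.erpr_pos_prob * np.exp(th_pos * z)
        lam_neg = config.baseline_hazard * (1 - config.erpr_pos_prob) * np.exp(th_neg * z)
        lam = lam_pos + lam_neg
        with np.errstate(divide="ignore"):
            t_event = rng.exponential(np.where(lam > 0, 1 / lam, np.inf))
        erpr_pos = rng.random(n) < lam_pos / np.where(lam > 0, lam, 1.0)

    lo = config.max_followup_years - config.enrollment_window_years
    t_admin = rng.uniform(lo, config.max_followup_years, size=n)
    if config.dropout_rate > 0:
        t_drop = rng.exponential(1 / config.dropout_rate, size=n)
    else:
        t_drop = np.full(n, np.inf)
    t_cens = np.minimum(t_admin, t_drop)
    event = t_event <= t_cens
    out = cohort.copy()
    out["followup_years"] = np.where(event, t_event, t_cens)
    out["event"] = event.astype(int)

    her2_pos = rng.random(n) < config.her2_pos_prob
    out["erpr_status"] = np.where(event, np.where(erpr_pos, "positive", "negative"), pd.NA)
    out["her2_status"] = np.where(event, np.where(her2_pos, "positive", "negative"), pd.NA)
    return out


def simulate_cohort(config: SimulationConfig):
    """Run the full generative chain.

    Returns ``(cohort, genotypes, variants, true_params)`` where the
    cohort carries phenotypes, covariates and outcomes.
    """
    variants, true = simulate_variants(config)
    genotypes = simulate_genotypes(variants, config.n_individuals, seed=config.rng(2))
    cohort = simulate_phenotypes(genotypes, true, config)
    cohort = simulate_outcomes(cohort, config)
    return cohort, genotypes, variants, true


def simulate_summary_stats(config: SimulationConfig) -> tuple[pd.DataFrame, TrueParameters]:
    """Two-sample per-variant summary statistics.

    gamma_hat_j ~ N(beta_j, se_gamma); Gamma_hat_j ~ N(theta * beta_j +
    pleiotropy_shift * [j invalid], se_big_gamma).  The invalid set is
    filled greedily in random order until it accounts for
    ``invalid_fraction`` of the total inverse-variance weight.
    """
    variants, true = simulate_variants(config)
    rng = config.rng(5)
    J = config.n_variants
    betas = true.per_variant_exposure_betas
    se_g = np.full(J, config.se_gamma)
    se_G = np.full(J, config.se_big_gamma)
    weights = 1 / np.maximum(se_G, 1e-12) ** 2
    target = config.invalid_fraction * weights.sum()
    order = rng.permutation(J)
    invalid = np.zeros(J, bool)
    cum = 0.0
    for j in order:
        if cum + 1e-9 >= target:
            break
        invalid[j] = True
        cum += weights[j]
    gamma_hat = rng.normal(betas, se_g)
    big_gamma_hat = rng.normal(true.theta * betas + config.pleiotropy_shift * invalid, se_G)
    df = pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in variants],
            "gamma_hat": gamma_hat,
            "se_gamma": se_g,
            "big_gamma_hat": big_gamma_hat,
            "se_big_gamma": se_G,
            "is_invalid": invalid,
        }
    )
    true = dataclasses.replace(
        true, invalid_variant_ids=frozenset(df.loc[invalid, "variant_id"])
    )
    return df, true


# ---------------------------------------------------------------------------
# I/O

def write_dosage_vcf(genotypes: pd.DataFrame, variants: list[VariantRecord], path) -> None:
    """Write dosages as a VCF with a per-sample DS field.

    The effect (exposure-raising) allele is written as ALT so dosages
    round-trip as ALT-allele counts.
    """
    samples = [str(i) for i in genotypes.index]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the ALT allele">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for v in sorted(variants, key=lambda r: (r.chrom, r.pos)):
            if v.variant_id not in genotypes.columns:
                continue
            ds = genotypes[v.variant_id].to_numpy(float)
            row = [v.chrom, str(v.pos), v.variant_id, v.other_allele, v.effect_allele, ".", "PASS", ".", "DS"]
            row += ["." if np.isnan(x) else f"{x:g}" for x in ds]
            fh.write("\t".join(row) + "\n")


def read_dosage_vcf(path) -> pd.DataFrame:
    """Read a DS-dosage VCF back into an individuals x variants frame."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    cols, ids = [], []
    for rec in vcf:
        ds = np.asarray(rec.format("DS"), float).reshape(-1)
        ids.append(rec.ID)
        cols.append(ds)
    return pd.DataFrame(np.column_stack(cols), index=vcf.samples, columns=ids)


def write_manifest(config: SimulationConfig, true_params: TrueParameters, path) -> None:
    """JSON manifest recording the configuration, seed and ground truth."""
    payload = {
        "config": dataclasses.asdict(config),
        "true_parameters": {
            "theta": true_params.theta,
            "per_variant_exposure_betas": np.asarray(true_params.per_variant_exposure_betas).tolist(),
            "invalid_variant_ids": sorted(true_params.invalid_variant_ids),
            "realized_r2": true_params.realized_r2,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
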