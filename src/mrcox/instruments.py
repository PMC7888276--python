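"""Genetic-instrument curation and the weighted allele score.

Operations on collections of :class:`VariantRecord`: genotype quality
control (missingness, Hardy-Weinberg, imputation quality), greedy LD
pruning, cross-study merging with allele harmonization, exclusion of
pleiotropic variants, effect-allele orientation, instrument-strength
F-statistics, and construction/rescaling of the weighted genetic score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateRegressionError,
    EmptyInstrumentError,
    HarmonizationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "GeneticScore",
    "DEFAULT_PLEIOTROPY_TRAITS",
    "qc_filter",
    "prune_ld",
    "merge_studies",
    "exclude_pleiotropic",
    "orient_effect_alleles",
    "f_statistic",
    "build_genetic_score",
    "rescale_gs",
    "read_instruments_tsv",
    "write_instruments_tsv",
]

#: Traits whose association with both the exposure and the outcome marks an
#: instrument as horizontally pleiotropic: obesity measures, glycaemic /
#: diabetic traits, and lipid traits.
DEFAULT_PLEIOTROPY_TRAITS = frozenset(
    {
        "BMI",
        "WHR",
        "fasting glucose",
        "fasting insulin",
        "2-h glucose",
        "T2DM",
        "LDL",
        "HDL",
        "total cholesterol",
        "triglycerides",
    }
)


@dataclass
class VariantRecord:
    """One genetic instrument with its exposure association.

    ``gamma_hat`` is the per-effect-allele exposure effect: either the
    change in natural-log CRP (mg/L) for continuous-scale instruments or
    the log-odds of chronic inflammation (CRP > 3.0 mg/L) for
    binary-scale instruments; the two scales are never pooled in one
    estimator run.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    gamma_hat: float
    se_gamma: float
    exposure_scale: str = "log-continuous"  # or "binary-logodds"
    source_study: str = ""
    publication_year: int = 0
    pleiotropy_tags: frozenset = field(default_factory=frozenset)
    ld_cluster: int | None = None

    def __post_init__(self):
        if self.se_gamma <= 0:
            raise ValueError(f"{self.variant_id}: se_gamma must be > 0")
        if not 0 < self.eaf < 1:
            raise ValueError(f"{self.variant_id}: eaf must be in (0,1)")
        if self.exposure_scale not in {"log-continuous", "binary-logodds"}:
            raise ValueError(f"{self.variant_id}: unknown exposure scale")
        self.pleiotropy_tags = frozenset(self.pleiotropy_tags)

    @property
    def strength(self) -> float:
        """Exposure-association strength |gamma_hat / se_gamma|."""
        return abs(self.gamma_hat / self.se_gamma)


@dataclass
class GeneticScore:
    """Weighted allele score: per-individual sum of gamma_hat * dosage."""

    values: pd.Series
    variant_ids: list
    weights: np.ndarray
    rescale_intercept: float = 0.0
    rescale_slope: float = 1.0
    rescaled: bool = False
    n_imputed_dosages: int = 0


def _hwe_chi2_p(dosages: np.ndarray) -> tuple[float, float]:
    """1-df chi-square Hardy-Weinberg test on hard genotype calls.

    Fractional dosages are rounded to the nearest genotype class; no
    continuity correction.
    """
    d = np.clip(np.round(dosages[~np.isnan(dosages)]), 0, 2)
    n = d.size
    if n == 0:
        return np.nan, np.nan
    counts = np.array([(d == 0).sum(), (d == 1).sum(), (d == 2).sum()], float)
    p = (counts[1] + 2 * counts[2]) / (2 * n)
    if p in (0.0, 1.0):
        return 0.0, 1.0  # monomorphic: trivially in equilibrium
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def qc_filter(
    genotypes: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    max_missing: float = 0.02,
    hwe_p_min: float = 1e-4,
    min_impute_r2: float = 0.6,
) -> tuple[list, pd.DataFrame]:
    """Variant quality control.

    A variant is retained iff its missing-call rate is < ``max_missing``,
    its Hardy-Weinberg p-value is >= ``hwe_p_min``, and its imputation
    quality is >= ``min_impute_r2``.  Variants with no imputation-quality
    entry are treated as directly genotyped and pass that check.

    Parameters
    ----------
    genotypes : DataFrame
        Individuals x variants dosage matrix; NaN marks a missing call.
    metadata : DataFrame, optional
        Indexed by variant_id with an optional ``impute_r2`` column.

    Returns
    -------
    retained : list of variant_id
    report : DataFrame with each variant's three metrics and verdict.
    """
    rows = []
    for vid in genotypes.columns:
        col = genotypes[vid].to_numpy(float)
        miss = float(np.isnan(col).mean())
        chi2, hwe_p = _hwe_chi2_p(col)
        r2 = np.nan
        if metadata is not None and "impute_r2" in metadata.columns and vid in metadata.index:
            r2 = metadata.loc[vid, "impute_r2"]
        ok = (
            miss < max_missing
            and (np.isnan(hwe_p) or hwe_p >= hwe_p_min)
            and (np.isnan(r2) or r2 >= min_impute_r2)
        )
        rows.append(
            {
                "variant_id": vid,
                "missing_rate": miss,
                "hwe_chi2": chi2,
                "hwe_p": hwe_p,
                "impute_r2": r2,
                "retained": bool(ok),
            }
        )
    report = pd.DataFrame(rows).set_index("variant_id")
    retained = list(report.index[report["retained"]])
    if not retained:
        logger.warning("qc_filter removed every variant")
    return retained, report


def prune_ld(
    variants: list[VariantRecord],
    genotypes: pd.DataFrame | None = None,
    corr: pd.DataFrame | None = None,
    threshold: float = 0.3,
) -> list[VariantRecord]:
    """Greedy LD pruning at squared dosage correlation < ``threshold``.

    Variants are ranked by exposure-association strength |gamma/se|
    (descending, ties broken lexicographically on variant_id) and accepted
    iff their r-squared with every already-accepted variant is below the
    threshold.  Constant-dosage variants have undefined correlation and
    are excluded with a warning.
    """
    if corr is None:
        if genotypes is None:
            raise ValueError("prune_ld needs genotypes or a correlation matrix")
        corr = genotypes.corr()
    order = sorted(variants, key=lambda v: (-v.strength, v.variant_id))
    accepted: list[VariantRecord] = []
    for v in order:
        r_col = corr[v.variant_id] if v.variant_id in corr else None
        if r_col is None or np.isnan(r_col.get(v.variant_id, np.nan)):
            logger.warning("prune_ld: %s has undefined correlation (constant dosage); excluded", v.variant_id)
            continue
        if all(r_col[a.variant_id] ** 2 < threshold for a in accepted):
            accepted.append(v)
    return accepted


def _alleles_flipped(a: VariantRecord, b: VariantRecord) -> bool:
    return a.effect_allele == b.other_allele and a.other_allele == b.effect_allele


def merge_studies(variants: list[VariantRecord]) -> list[VariantRecord]:
    """Collapse duplicate variant_ids across source studies.

    The record from the most recent publication wins; ties go to the
    smaller standard error.  A duplicate whose alleles are swapped
    relative to the kept record is first reconciled by an allele flip
    (sign-flipped effect, complemented frequency).  Irreconcilable
    alleles raise :class:`HarmonizationError`.
    """
    by_id: dict[str, VariantRecord] = {}
    for v in variants:
        cur = by_id.get(v.variant_id)
        if cur is None:
            by_id[v.variant_id] = v
            continue
        same = (v.effect_allele == cur.effect_allele and v.other_allele == cur.other_allele)
        if not same and _alleles_flipped(v, cur):
            v = replace(
                v,
                effect_allele=cur.effect_allele,
                other_allele=cur.other_allele,
                eaf=1 - v.eaf,
                gamma_hat=-v.gamma_hat,
            )
        elif not same:
            raise HarmonizationError(
                f"{v.variant_id}: alleles {v.effect_allele}/{v.other_allele} vs "
                f"{cur.effect_allele}/{cur.other_allele} cannot be reconciled"
            )
        keep, drop = ((v, cur) if (v.publication_year, -v.se_gamma) > (cur.publication_year, -cur.se_gamma) else (cur, v))
        logger.info(
            "merge_studies: %s keeping %s (%d), discarding %s (%d)",
            keep.variant_id, keep.source_study, keep.publication_year,
            drop.source_study, drop.publication_year,
        )
        by_id[keep.variant_id] = keep
    return list(by_id.values())


def exclude_pleiotropic(
    variants: list[VariantRecord],
    excluded_traits: frozenset = DEFAULT_PLEIOTROPY_TRAITS,
) -> list[VariantRecord]:
    """Drop variants tagged with any trait in ``excluded_traits``."""
    excluded_traits = frozenset(excluded_traits)
    return [v for v in variants if not (v.pleiotropy_tags & excluded_traits)]


def orient_effect_alleles(variants: list[VariantRecord]) -> list[VariantRecord]:
    """Orient every record so the effect allele is exposure-raising.

    Records with a negative exposure effect have their alleles swapped,
    the effect-allele frequency complemented and the effect negated.
    Idempotent: an oriented list passes through unchanged.
    """
    out = []
    for v in variants:
        if v.gamma_hat < 0:
            v = replace(
                v,
                effect_allele=v.other_allele,
                other_allele=v.effect_allele,
                eaf=1 - v.eaf,
                gamma_hat=-v.gamma_hat,
            )
        out.append(v)
    return out


def f_statistic(r2: float, n: int, k: int) -> tuple[float, bool]:
    """Instrument-strength F-statistic.

    F = (r2 / (1 - r2)) * ((n - k - 1) / k) for an exposure regression on
    ``k`` instruments in ``n`` individuals explaining a fraction ``r2``
    of variance.  Returns ``(F, weak)`` where ``weak`` flags F below the
    conventional threshold of 10.
    """
    if not 0 <= r2 < 1:
        raise ValueError("r2 must be in [0, 1)")
    if n <= k + 1 or k < 1:
        raise ValueError("need n > k + 1 >= 2")
    f = (r2 / (1 - r2)) * ((n - k - 1) / k)
    return f, f < 10


def build_genetic_score(
    genotypes: pd.DataFrame,
    variants: list[VariantRecord],
) -> GeneticScore:
    """Weighted allele score GS_i = sum_j gamma_hat_j * dosage_ij.

    Dosages must be counted on the oriented (exposure-raising) effect
    allele.  Missing dosages are mean-imputed at 2 * eaf, with the
    imputed count recorded on the returned score.
    """
    usable = [v for v in variants if v.variant_id in genotypes.columns]
    if not usable:
        raise EmptyInstrumentError("no overlap between genotype columns and instrument weights")
    ids = [v.variant_id for v in usable]
    w = np.array([v.gamma_hat for v in usable])
    dos = genotypes[ids].to_numpy(float).copy()
    nan_mask = np.isnan(dos)
    n_imp = int(nan_mask.sum())
    if n_imp:
        fill = np.array([2 * v.eaf for v in usable])
        dos[nan_mask] = np.broadcast_to(fill, dos.shape)[nan_mask]
        logger.info("build_genetic_score: mean-imputed %d missing dosages", n_imp)
    values = pd.Series(dos @ w, index=genotypes.index, name="gs")
    return GeneticScore(values=values, variant_ids=ids, weights=w, n_imputed_dosages=n_imp)


def rescale_gs(
    gs: GeneticScore,
    exposure: pd.Series,
    non_case_mask: pd.Series | np.ndarray,
) -> tuple[GeneticScore, tuple[float, float]]:
    """Rescale the score to exposure units among unaffected individuals.

    Ordinary least squares of the exposure (log-CRP) on the raw score is
    fit among non-cases only; the fitted line ``b0 + b1 * GS`` is then
    applied to everyone.  The rescaled score is a positive affine
    transform of the raw score whenever ``b1 > 0``, so the two are
    perfectly correlated (r = 1.0); a non-positive slope is flagged.
    """
    mask = np.asarray(non_case_mask, bool)
    if mask.sum() < 3:
        raise DegenerateRegressionError("need at least 3 non-case individuals")
    x = gs.values.to_numpy(float)[mask]
    y = np.asarray(exposure, float)[mask]
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise DegenerateRegressionError("genetic score constant among non-cases")
    b1, b0 = np.polyfit(x, y, 1)
    if b1 <= 0:
        logger.warning("rescale_gs: non-positive slope %.3g; rescaled score is anti-correlated", b1)
    rescaled = GeneticScore(
        values=b0 + b1 * gs.values,
        variant_ids=list(gs.variant_ids),
        weights=gs.weights.copy(),
        rescale_intercept=float(b0),
        rescale_slope=float(b1),
        rescaled=True,
        n_imputed_dosages=gs.n_imputed_dosages,
    )
    return rescaled, (float(b0), float(b1))


# ---------------------------------------------------------------------------
# TSV round-trip

_TSV_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele", "eaf",
    "beta", "se", "scale", "study", "year", "pleiotropy_tags",
]


def write_instruments_tsv(variants: list[VariantRecord], path) -> None:
    rows = [
        {
            "variant_id": v.variant_id, "chrom": v.chrom, "pos": v.pos,
            "effect_allele": v.effect_allele, "other_allele": v.other_allele,
            "eaf": v.eaf, "beta": v.gamma_hat, "se": v.se_gamma,
            "scale": v.exposure_scale, "study": v.source_study,
            "year": v.publication_year,
            "pleiotropy_tags": ";".join(sorted(v.pleiotropy_tags)),
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_instruments_tsv(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"instruments TSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        tags = frozenset(t for t in str(row.pleiotropy_tags).split(";") if t and t != "nan")
        out.append(
            VariantRecord(
                variant_id=row.variant_id, chrom=str(row.chrom), pos=int(row.pos),
                effect_allele=row.effect_allele, other_allele=row.other_allele,
                eaf=float(row.eaf), gamma_hat=float(row.beta), se_gamma=float(row.se),
                exposure_scale=row.scale,
                source_study="" if pd.isna(row.study) else str(row.study),
                publication_year=int(row.year), pleiotropy_tags=tags,
            )
        )
    return out
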