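"""Per-variant survival associations.

Each instrument's association with time to event is estimated by Cox
proportional-hazards regression (Efron tie handling, via lifelines) under
two adjustment stages — (1) age and 10 genetic principal components,
(2) additionally the lifestyle/demographic covariate set — separately
within each sub-study, with a Schoenfeld-residual proportional-hazards
check, and pooled across sub-studies by fixed-effect inverse-variance
meta-analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .exceptions import NoEstimatesError, NoEventsError

logger = logging.getLogger(__name__)

__all__ = [
    "SNPOutcomeEstimate",
    "STAGE1_COVARIATES",
    "STAGE2_COVARIATES",
    "fit_cox_per_snp",
    "fit_cox",
    "check_proportional_hazards",
    "fixed_effect_meta",
    "estimate_all_snps",
    "hazard_ratio",
]

STAGE1_COVARIATES = ["age"] + [f"pc{k}" for k in range(1, 11)]

#: lifestyle/demographic adjustment added at stage 2
_LIFESTYLE = [
    "education",
    "family_income",
    "family_history",
    "cesd_score",
    "cigarettes_per_day",
    "met_hours_week",
    "alcohol_g_day",
    "sfa_pct_calories",
    "age_menopause",
    "oc_years",
    "e_only_years",
    "ep_years",
    "height_cm",
    "weight_kg",
    "waist_cm",
]
STAGE2_COVARIATES = STAGE1_COVARIATES + _LIFESTYLE


@dataclass
class SNPOutcomeEstimate:
    """Log hazard ratio per effect-allele dosage for one variant."""

    variant_id: str
    stage: int
    substudy: str  # sub-study label or "pooled"
    log_hr: float
    se: float
    n: int = 0
    events: int = 0
    schoenfeld_rho: float = np.nan
    schoenfeld_p: float = np.nan

    @property
    def flagged(self) -> bool:
        """True when the fit failed (separation / non-convergence)."""
        return not np.isfinite(self.se) or not np.isfinite(self.log_hr)


def _covariates_for_stage(stage: int) -> list[str]:
    if stage == 1:
        return STAGE1_COVARIATES
    if stage == 2:
        return STAGE2_COVARIATES
    raise ValueError("stage must be 1 or 2")


def fit_cox(
    data: pd.DataFrame,
    exposure_col: str,
    covariates: list[str],
    duration_col: str = "followup_years",
    event_col: str = "event",
    check_ph: bool = True,
) -> tuple[float, float, float, float, CoxPHFitter | None]:
    """Cox fit of one exposure column with adjustment covariates.

    Returns ``(log_hr, se, schoenfeld_rho, schoenfeld_p, fitter)``;
    a failed fit returns NaN/inf sentinels and ``None``.  Complete-case
    rows only; the dropped-row count is logged.
    """
    cols = [exposure_col, *covariates, duration_col, event_col]
    df = data[cols].astype(float)
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        logger.info("fit_cox(%s): dropped %d incomplete rows", exposure_col, n0 - len(df))
    if df[event_col].sum() == 0:
        raise NoEventsError(f"no events for {exposure_col}")
    # drop constant adjustment columns (zero variance breaks the solver)
    keep = [exposure_col] + [c for c in covariates if df[c].nunique() > 1]
    try:
        cph = CoxPHFitter()
        cph.fit(df[keep + [duration_col, event_col]], duration_col=duration_col, event_col=event_col)
    except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
        logger.warning("fit_cox(%s): %s; flagged", exposure_col, exc)
        return np.nan, np.inf, np.nan, np.nan, None
    log_hr = float(cph.params_[exposure_col])
    se = float(cph.standard_errors_[exposure_col])
    rho = p = np.nan
    if check_ph:
        rho, p = check_proportional_hazards(cph, df, exposure_col, duration_col, event_col)
    return log_hr, se, rho, p, cph


def check_proportional_hazards(
    fitter: CoxPHFitter,
    data: pd.DataFrame,
    exposure_col: str,
    duration_col: str = "followup_years",
    event_col: str = "event",
) -> tuple[float, float]:
    """Schoenfeld-residual proportional-hazards diagnostic.

    Pearson correlation rho between the scaled Schoenfeld residuals of
    the exposure term and the rank of the event times, with its
    two-sided test p-value.  Needs >= 2 events; otherwise returns
    ``(nan, nan)`` with a warning.
    """
    if data[event_col].sum() < 2:
        logger.warning("check_proportional_hazards: fewer than 2 events; undefined")
        return np.nan, np.nan
    resid = fitter.compute_residuals(data, kind="scaled_schoenfeld")
    r = resid[exposure_col].to_numpy(float)
    times = data.loc[resid.index, duration_col].to_numpy(float)
    ranks = stats.rankdata(times)
    if len(r) < 3 or np.std(r) == 0:
        return np.nan, np.nan
    rho, p = stats.pearsonr(ranks, r)
    return float(rho), float(p)


def fit_cox_per_snp(
    cohort: pd.DataFrame,
    genotypes: pd.DataFrame,
    variant_id: str,
    stage: int,
    by_substudy: bool = True,
    check_ph: bool = True,
) -> list[SNPOutcomeEstimate]:
    """Per-sub-study Cox estimates for one variant's dosage."""
    covs = _covariates_for_stage(stage)
    df = cohort.copy()
    df["_dosage"] = genotypes[variant_id].reindex(df.index).to_numpy(float)
    groups = df.groupby("substudy", observed=True) if by_substudy else [("all", df)]
    out = []
    for label, sub in groups:
        if sub["event"].sum() == 0:
            logger.warning("fit_cox_per_snp(%s, %s): no events; skipped", variant_id, label)
            continue
        if sub["_dosage"].nunique() <= 1:
            logger.warning("fit_cox_per_snp(%s, %s): constant dosage; skipped", variant_id, label)
            continue
        log_hr, se, rho, p, _ = fit_cox(sub, "_dosage", covs, check_ph=check_ph)
        out.append(
            SNPOutcomeEstimate(
                variant_id=variant_id,
                stage=stage,
                substudy=str(label),
                log_hr=log_hr,
                se=se,
                n=len(sub),
                events=int(sub["event"].sum()),
                schoenfeld_rho=rho,
                schoenfeld_p=p,
            )
        )
    return out


def fixed_effect_meta(estimates: list[SNPOutcomeEstimate]) -> SNPOutcomeEstimate:
    """Inverse-variance fixed-effect pooling across sub-studies.

    Flagged (non-converged) inputs are excluded; pooling a single study
    returns it unchanged apart from the "pooled" label.
    """
    usable = [e for e in estimates if not e.flagged]
    if not usable:
        raise NoEstimatesError("no usable estimates to pool")
    g = np.array([e.log_hr for e in usable])
    se = np.array([e.se for e in usable])
    w = 1 / se**2
    pooled = float((w * g).sum() / w.sum())
    pooled_se = float(np.sqrt(1 / w.sum()))
    return SNPOutcomeEstimate(
        variant_id=usable[0].variant_id,
        stage=usable[0].stage,
        substudy="pooled",
        log_hr=pooled,
        se=pooled_se,
        n=sum(e.n for e in usable),
        events=sum(e.events for e in usable),
    )


def estimate_all_snps(
    cohort: pd.DataFrame,
    genotypes: pd.DataFrame,
    variant_ids=None,
    stage: int = 1,
    by_substudy: bool = True,
    check_ph: bool = False,
) -> pd.DataFrame:
    """Pooled per-variant estimates as a tidy frame.

    One row per variant with the meta-analysed (or single-model) log
    hazard ratio; variants whose every sub-study fit failed are
    reported with NaN/inf sentinels and excluded downstream.
    """
    ids = list(variant_ids) if variant_ids is not None else list(genotypes.columns)
    rows = []
    for vid in ids:
        per_study = fit_cox_per_snp(cohort, genotypes, vid, stage, by_substudy=by_substudy, check_ph=check_ph)
        try:
            pooled = fixed_effect_meta(per_study)
        except NoEstimatesError:
            logger.warning("estimate_all_snps: %s has no usable fit; sentinel row", vid)
            rows.append({"variant_id": vid, "stage": stage, "log_hr": np.nan, "se": np.inf,
                         "n": 0, "events": 0, "schoenfeld_rho": np.nan, "schoenfeld_p": np.nan})
            continue
        rows.append(
            {
                "variant_id": vid,
                "stage": stage,
                "log_hr": pooled.log_hr,
                "se": pooled.se,
                "n": pooled.n,
                "events": pooled.events,
                "schoenfeld_rho": np.nanmean([e.schoenfeld_rho for e in per_study]) if check_ph else np.nan,
                "schoenfeld_p": np.nan if not check_ph else float(np.nanmin([e.schoenfeld_p for e in per_study])),
            }
        )
    return pd.DataFrame(rows).set_index("variant_id")


def hazard_ratio(log_hr: float, se: float, z: float = 1.959963984540054) -> tuple[float, float, float]:
    """HR with normal-theory 95% CI: exp(log_hr -/+ z * se)."""
    return float(np.exp(log_hr)), float(np.exp(log_hr - z * se)), float(np.exp(log_hr + z * se))
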