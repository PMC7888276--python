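"""MR gene-environment interaction (G x E) corrected estimate.

When the genetic score's association with the exposure varies across
environment strata while any pleiotropic pathway stays constant, the
causal effect is identified as the slope of the stratum-level score-
outcome associations (Gamma_s, Cox log hazard ratio per unit score) on
the stratum-level score-exposure associations (gamma_s, linear slope of
log-CRP on the score).  The intercept estimates the constant pleiotropic
effect, so the slope is "corrected" for pleiotropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import InsufficientStrataError, UnidentifiedError
from .snp_outcome import _covariates_for_stage, fit_cox
from .strata import StratumSpec, assign_strata

logger = logging.getLogger(__name__)

__all__ = ["StratumAssociation", "GxEEstimate", "stratum_associations", "gxe_estimate"]


@dataclass
class StratumAssociation:
    """Score-exposure and score-outcome associations within one stratum."""

    stratum_label: str
    gamma_s: float
    se_gamma_s: float
    big_gamma_s: float
    se_big_gamma_s: float
    n_s: int
    events_s: int


@dataclass
class GxEEstimate:
    """Corrected causal slope and constant-pleiotropy intercept."""

    slope: float
    se_slope: float
    p_slope: float
    intercept: float
    se_intercept: float
    p_intercept: float
    n_strata: int


def stratum_associations(
    cohort: pd.DataFrame,
    gs_values: pd.Series,
    spec: StratumSpec,
    stage: int = 1,
    exposure_col: str = "log_crp",
) -> list[StratumAssociation]:
    """Per-stratum genetic-score associations.

    Within each stratum of ``spec``: OLS of the exposure on the score
    (gamma_s) and a Cox regression of the outcome on the score with the
    stage's adjustment covariates (Gamma_s).  Strata with no events or a
    constant score are dropped with a warning; fewer than two usable
    strata raises :class:`InsufficientStrataError`.
    """
    labels = assign_strata(cohort, spec)
    covs = _covariates_for_stage(stage)
    out = []
    for label in [l for l in pd.unique(labels.dropna())]:
        sub = cohort[labels == label].copy()
        sub["_gs"] = gs_values.reindex(sub.index).to_numpy(float)
        events = int(sub["event"].sum())
        if events == 0:
            logger.warning("stratum_associations: %s=%s has no events; dropped", spec.variable, label)
            continue
        if sub["_gs"].nunique() <= 1:
            logger.warning("stratum_associations: %s=%s has constant score; dropped", spec.variable, label)
            continue
        X = sm.add_constant(sub["_gs"].to_numpy(float))
        ols = sm.OLS(sub[exposure_col].to_numpy(float), X).fit()
        gamma_s, se_gamma_s = ols.params[1], ols.bse[1]
        log_hr, se, _, _, _ = fit_cox(sub, "_gs", covs, check_ph=False)
        if not np.isfinite(se):
            logger.warning("stratum_associations: %s=%s Cox fit failed; dropped", spec.variable, label)
            continue
        out.append(
            StratumAssociation(
                stratum_label=str(label),
                gamma_s=float(gamma_s),
                se_gamma_s=float(se_gamma_s),
                big_gamma_s=float(log_hr),
                se_big_gamma_s=float(se),
                n_s=len(sub),
                events_s=events,
            )
        )
    if len(out) < 2:
        raise InsufficientStrataError(
            f"{spec.variable}: only {len(out)} usable strata (need >= 2)"
        )
    return out


def gxe_estimate(associations: list[StratumAssociation]) -> GxEEstimate:
    """Weighted least squares of Gamma_s on gamma_s across strata.

    Weights are 1/se(Gamma_s)^2 with an unscaled (fixed-effect)
    covariance; with exactly two strata this reduces to the closed form
    slope = (Gamma_2 - Gamma_1)/(gamma_2 - gamma_1).  Identical gamma_s
    across strata leaves the slope unidentified and raises
    :class:`UnidentifiedError`.
    """
    if len(associations) < 2:
        raise InsufficientStrataError("gxe_estimate needs >= 2 strata")
    g = np.array([a.gamma_s for a in associations])
    G = np.array([a.big_gamma_s for a in associations])
    w = np.array([1 / a.se_big_gamma_s**2 for a in associations])
    if np.ptp(g) == 0:
        raise UnidentifiedError("no heterogeneity in score-exposure strength across strata")
    X = np.column_stack([np.ones_like(g), g])
    cov = np.linalg.inv(X.T @ (w[:, None] * X))
    coef = cov @ (X.T @ (w * G))
    intercept, slope = coef
    se_int, se_slope = np.sqrt(np.diag(cov))
    p_slope = 2 * stats.norm.sf(abs(slope) / se_slope) if se_slope > 0 else np.nan
    p_int = 2 * stats.norm.sf(abs(intercept) / se_int) if se_int > 0 else np.nan
    return GxEEstimate(
        slope=float(slope),
        se_slope=float(se_slope),
        p_slope=float(p_slope),
        intercept=float(intercept),
        se_intercept=float(se_int),
        p_intercept=float(p_int),
        n_strata=len(associations),
    )
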