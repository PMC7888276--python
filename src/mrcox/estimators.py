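"""Summary-statistic Mendelian randomization estimators.

Given per-variant SNP-exposure effects gamma_j (with SE) and SNP-outcome
log hazard ratios Gamma_j (with SE), this module provides:

* per-variant Wald ratios beta_j = Gamma_j / gamma_j with first- or
  second-order delta-method standard errors;
* the fixed-effect inverse-variance-weighted (IVW) estimate;
* the weighted median (WM), consistent while valid instruments carry a
  majority (> 50%) of the inverse-variance weight;
* the penalized weighted median (PWM), which first down-weights
  instruments with outlying heterogeneity contributions;
* MR-Egger regression, whose intercept tests directional pleiotropy;
* Cochran's Q heterogeneity statistic.

All pooled estimates are on the log hazard-ratio scale per unit exposure
(log-odds of chronic inflammation, or natural-log CRP in mg/L) and are
reported alongside the exponentiated hazard ratio with a normal-theory
95% interval.  The weighted-median family obtains standard errors by a
seeded parametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    InsufficientInstrumentsError,
    NoEstimatesError,
    UndefinedRatioError,
)

__all__ = [
    "RatioEstimate",
    "MRResult",
    "wald_ratio",
    "wald_ratios",
    "ivw",
    "weighted_median",
    "penalized_weighted_median",
    "mr_egger",
    "cochran_q",
    "report_hr",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class RatioEstimate:
    """Per-variant Wald ratio with its inverse-variance weight."""

    variant_id: str
    ratio: float
    se_ratio: float
    q_contribution: float = np.nan

    def __post_init__(self):
        if self.se_ratio <= 0 or not np.isfinite(self.se_ratio):
            raise ValueError(f"{self.variant_id}: se_ratio must be finite and > 0")

    @property
    def weight(self) -> float:
        return 1.0 / self.se_ratio**2


@dataclass
class MRResult:
    """One pooled MR estimate on the log hazard-ratio scale."""

    method: str
    estimate: float
    se: float
    n_instruments: int
    ci_low: float = np.nan
    ci_high: float = np.nan
    p: float = np.nan
    hr: float = np.nan
    hr_low: float = np.nan
    hr_high: float = np.nan
    Q: float = np.nan
    Q_df: int = 0
    Q_p: float = np.nan
    boot_reps: int = 0
    seed: int | None = None
    exposure_scale: str = ""


def _finalize(res: MRResult) -> MRResult:
    """Attach normal-theory CI, p-value, and the hazard-ratio scale."""
    ci_low = res.estimate - _Z95 * res.se
    ci_high = res.estimate + _Z95 * res.se
    p = 2 * stats.norm.sf(abs(res.estimate) / res.se) if res.se > 0 else np.nan
    return replace(
        res,
        ci_low=ci_low,
        ci_high=ci_high,
        p=float(p),
        hr=float(np.exp(res.estimate)),
        hr_low=float(np.exp(ci_low)),
        hr_high=float(np.exp(ci_high)),
    )


def report_hr(res: MRResult) -> MRResult:
    """Fill the hazard-ratio fields from the log-scale estimate and SE."""
    return _finalize(res)


def wald_ratio(
    gamma_hat: float,
    se_gamma: float,
    big_gamma_hat: float,
    se_big_gamma: float,
    variant_id: str = "",
    order: str = "first",
    cov_gamma_big_gamma: float = 0.0,
) -> RatioEstimate:
    """Per-variant causal estimate Gamma / gamma.

    The first-order (default) delta-method SE is se_Gamma / |gamma|; the
    second-order SE adds the exposure-uncertainty term
    Gamma^2 se_gamma^2 / gamma^4.  ``cov_gamma_big_gamma`` optionally
    enters the second-order variance as -2 Gamma cov / gamma^3, for
    one-sample overlap between the exposure and outcome samples.
    """
    if gamma_hat == 0:
        raise UndefinedRatioError(f"{variant_id or 'variant'}: gamma_hat is zero")
    ratio = big_gamma_hat / gamma_hat
    if order == "first":
        se = se_big_gamma / abs(gamma_hat)
    elif order == "second":
        var = (
            se_big_gamma**2 / gamma_hat**2
            + big_gamma_hat**2 * se_gamma**2 / gamma_hat**4
            - 2 * big_gamma_hat * cov_gamma_big_gamma / gamma_hat**3
        )
        se = float(np.sqrt(max(var, 0.0)))
    else:
        raise ValueError("order must be 'first' or 'second'")
    return RatioEstimate(variant_id=variant_id, ratio=float(ratio), se_ratio=float(se))


def wald_ratios(summary: pd.DataFrame, order: str = "first") -> list[RatioEstimate]:
    """Wald ratios for every row of a summary-statistics frame.

    Expects columns ``variant_id, gamma_hat, se_gamma, big_gamma_hat,
    se_big_gamma``; rows with zero gamma_hat or non-finite outcome SE
    are skipped.
    """
    out = []
    for row in summary.itertuples(index=False):
        if row.gamma_hat == 0 or not np.isfinite(row.se_big_gamma) or not np.isfinite(row.big_gamma_hat):
            continue
        out.append(
            wald_ratio(row.gamma_hat, row.se_gamma, row.big_gamma_hat, row.se_big_gamma,
                       variant_id=row.variant_id, order=order)
        )
    return out


def _arrays(ratios: list[RatioEstimate]):
    b = np.array([r.ratio for r in ratios])
    se = np.array([r.se_ratio for r in ratios])
    return b, se, 1 / se**2


def ivw(ratios: list[RatioEstimate]) -> MRResult:
    """Fixed-effect inverse-variance-weighted estimate.

    Equivalent to the slope of a weighted regression of Gamma on gamma
    through the origin with weights 1/se_Gamma^2.
    """
    if not ratios:
        raise NoEstimatesError("ivw: no instruments")
    b, se, w = _arrays(ratios)
    est = float((w * b).sum() / w.sum())
    se_est = float(np.sqrt(1 / w.sum()))
    q, df, qp = _cochran_q_arrays(b, w)
    return _finalize(
        MRResult("IVW", est, se_est, len(ratios), Q=q, Q_df=df, Q_p=qp)
    )


def _weighted_median_core(b: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median of ratio estimates.

    Sort estimates ascending; at normalized cumulative weight
    p_j = (S_j - w_j/2) / S_total, interpolate linearly to p = 0.5.
    """
    order = np.argsort(b)
    b, w = b[order], w[order]
    s = np.cumsum(w)
    p = (s - w / 2) / s[-1]
    return float(np.interp(0.5, p, b))


def _weighted_median_rows(b: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise weighted medians of a (reps x J) matrix (shared or per-row weights)."""
    if w.ndim == 1:
        w = np.broadcast_to(w, b.shape)
    order = np.argsort(b, axis=1)
    bs = np.take_along_axis(b, order, axis=1)
    ws = np.take_along_axis(w, order, axis=1)
    s = np.cumsum(ws, axis=1)
    p = (s - ws / 2) / s[:, -1:]
    out = np.empty(b.shape[0])
    for i in range(b.shape[0]):
        out[i] = np.interp(0.5, p[i], bs[i])
    return out


def _penalized_weights(b: np.ndarray, se: np.ndarray, penalty: float) -> np.ndarray:
    """Down-weight instruments with outlying heterogeneity contributions.

    q_j = w_j (b_j - IVW)^2 is referred to the chi-square(1) upper tail;
    weights become w_j * min(1, penalty * p_j).
    """
    w = 1 / se**2
    est = (w * b).sum() / w.sum()
    q = w * (b - est) ** 2
    p = stats.chi2.sf(q, df=1)
    return w * np.minimum(1.0, penalty * p)


def _bootstrap_se(
    b: np.ndarray,
    se: np.ndarray,
    boot_reps: int,
    seed,
    penalty: float | None = None,
    center: np.ndarray | float | None = None,
) -> float:
    """Parametric-bootstrap SE of the (penalized) weighted median.

    With ``center`` set (default in the callers: the point estimate),
    draws are N(center, se_j): the bootstrap population reproduces the
    estimator's sampling dispersion without double-counting the noise
    already present in the observed ratios.  ``center=None`` draws
    around the observed ratios N(b_j, se_j) — the scheme common in
    two-sample MR software — which over-disperses the bootstrap
    population and yields conservative intervals.
    """
    rng = np.random.default_rng(seed)
    loc = b if center is None else center
    draws = rng.normal(loc, se, size=(boot_reps, b.size))
    if penalty is None:
        w = 1 / se**2
        ests = _weighted_median_rows(draws, w)
    else:
        # re-penalize within each draw so the SE reflects the full procedure
        w = 1 / se**2
        ivw_r = (draws * w).sum(axis=1) / w.sum()
        q = w * (draws - ivw_r[:, None]) ** 2
        pvals = stats.chi2.sf(q, df=1)
        w_star = w * np.minimum(1.0, penalty * pvals)
        ests = _weighted_median_rows(draws, w_star)
    return float(ests.std(ddof=1))


def weighted_median(
    ratios: list[RatioEstimate],
    boot_reps: int = 1000,
    seed: int = 0,
    boot_center: str = "consensus",
) -> MRResult:
    """Weighted-median estimate with parametric-bootstrap SE.

    Consistent as long as instruments carrying more than half of the
    total inverse-variance weight are valid.  ``boot_center`` selects
    the bootstrap population: ``"consensus"`` (default, draws around
    the point estimate; calibrated coverage) or ``"observed"`` (draws
    around each observed ratio; conservative).
    """
    if len(ratios) < 2:
        raise InsufficientInstrumentsError("weighted_median needs >= 2 instruments")
    b, se, w = _arrays(ratios)
    est = _weighted_median_core(b, w)
    center = est if boot_center == "consensus" else None
    se_est = _bootstrap_se(b, se, boot_reps, seed, center=center)
    q, df, qp = _cochran_q_arrays(b, w)
    return _finalize(
        MRResult("WM", est, se_est, len(ratios), Q=q, Q_df=df, Q_p=qp,
                 boot_reps=boot_reps, seed=seed)
    )


def penalized_weighted_median(
    ratios: list[RatioEstimate],
    penalty_constant: float = 20.0,
    boot_reps: int = 1000,
    seed: int = 0,
    boot_center: str = "consensus",
) -> MRResult:
    """Weighted median after penalizing heterogeneous instruments.

    Instruments whose Cochran-Q contribution is improbably large under
    chi-square(1) get weight w_j * penalty * p_j; homogeneous sets
    (all p_j >= 1/penalty) reproduce the plain weighted median exactly.
    The penalization is recomputed inside every bootstrap draw.
    """
    if len(ratios) < 2:
        raise InsufficientInstrumentsError("penalized_weighted_median needs >= 2 instruments")
    b, se, w = _arrays(ratios)
    w_star = _penalized_weights(b, se, penalty_constant)
    est = _weighted_median_core(b, w_star)
    center = est if boot_center == "consensus" else None
    se_est = _bootstrap_se(b, se, boot_reps, seed, penalty=penalty_constant, center=center)
    q, df, qp = _cochran_q_arrays(b, w)
    return _finalize(
        MRResult("PWM", est, se_est, len(ratios), Q=q, Q_df=df, Q_p=qp,
                 boot_reps=boot_reps, seed=seed)
    )


def mr_egger(
    gammas: np.ndarray,
    big_gammas: np.ndarray,
    se_big_gammas: np.ndarray,
    constrain_intercept: bool = False,
) -> tuple[MRResult, MRResult | None]:
    """MR-Egger weighted regression of Gamma on gamma with intercept.

    Weighted least squares with fixed-effect weights 1/se_Gamma^2; the
    slope estimates the causal effect and a non-zero intercept indicates
    directional pleiotropy.  gamma must be oriented non-negative so the
    intercept's sign is interpretable.  With ``constrain_intercept`` the
    through-origin slope (identical to IVW under the same weights) is
    returned and the intercept result is None.
    """
    g = np.asarray(gammas, float)
    G = np.asarray(big_gammas, float)
    seG = np.asarray(se_big_gammas, float)
    if g.size < 3:
        raise InsufficientInstrumentsError("mr_egger needs >= 3 instruments")
    if np.any(g < 0):
        raise ValueError("mr_egger: orient gammas non-negative first")
    w = 1 / seG**2
    if constrain_intercept:
        slope = float((w * g * G).sum() / (w * g**2).sum())
        se_slope = float(np.sqrt(1 / (w * g**2).sum()))
        return _finalize(MRResult("Egger-slope", slope, se_slope, g.size)), None
    X = np.column_stack([np.ones_like(g), g])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * G)
    cov = np.linalg.inv(xtwx)
    coef = cov @ xtwy
    intercept, slope = coef
    se_int, se_slope = np.sqrt(np.diag(cov))
    slope_res = _finalize(MRResult("Egger-slope", float(slope), float(se_slope), g.size))
    int_res = _finalize(MRResult("Egger-intercept", float(intercept), float(se_int), g.size))
    return slope_res, int_res


def _cochran_q_arrays(b: np.ndarray, w: np.ndarray) -> tuple[float, int, float]:
    if b.size < 2:
        return np.nan, 0, np.nan
    est = (w * b).sum() / w.sum()
    q = float((w * (b - est) ** 2).sum())
    df = b.size - 1
    return q, df, float(stats.chi2.sf(q, df=df))


def cochran_q(ratios: list[RatioEstimate]) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic about the IVW estimate.

    Q = sum_j w_j (b_j - IVW)^2 on J - 1 degrees of freedom; large Q is
    additional evidence of pleiotropy.  Undefined for fewer than two
    instruments.
    """
    if len(ratios) < 2:
        raise InsufficientInstrumentsError("cochran_q needs >= 2 instruments")
    b, _, w = _arrays(ratios)
    return _cochran_q_arrays(b, w)
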