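"""End-to-end orchestration: stratified and subtype MR analyses.

Glues the stages together: per-variant exposure associations from
individual-level data, per-variant Cox outcome associations pooled over
sub-studies, Wald ratios, and the estimator battery (IVW, weighted
median, penalized weighted median, MR-Egger, Cochran's Q) — run overall,
within lifestyle strata, and within cause-specific tumour subtypes, with
Benjamini-Hochberg correction applied per analysis family.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

from . import estimators as est
from .exceptions import NoEventsError
from .instruments import VariantRecord, exclude_pleiotropic
from .snp_outcome import estimate_all_snps
from .strata import StratumSpec, assign_strata, default_strata

logger = logging.getLogger(__name__)

__all__ = [
    "exposure_associations",
    "run_mr",
    "run_stratified_mr",
    "subtype_analysis",
    "bh_adjust",
    "render_results",
    "default_strata",
]

_METHODS = ("IVW", "WM", "PWM", "Egger")


def exposure_associations(
    cohort: pd.DataFrame,
    genotypes: pd.DataFrame,
    variant_ids=None,
    exposure_col: str = "log_crp",
) -> pd.DataFrame:
    """Per-variant simple regression of the exposure on dosage.

    Vectorized ordinary least squares of ``exposure_col`` on each dosage
    column separately, returning slope (gamma_hat) and SE per variant.
    """
    ids = list(variant_ids) if variant_ids is not None else list(genotypes.columns)
    X = genotypes[ids].reindex(cohort.index).to_numpy(float)
    y = cohort[exposure_col].to_numpy(float)
    n = len(y)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (xc * yc[:, None]).sum(axis=0) / sxx
        resid_ss = (yc**2).sum() - slope**2 * sxx
        se = np.sqrt(resid_ss / (n - 2) / sxx)
    return pd.DataFrame({"gamma_hat": slope, "se_gamma": se}, index=pd.Index(ids, name="variant_id"))


def _summary_frame(
    cohort: pd.DataFrame,
    genotypes: pd.DataFrame,
    variants: list[VariantRecord],
    stage: int,
    by_substudy: bool,
    gammas_from_cohort: bool,
) -> pd.DataFrame:
    ids = [v.variant_id for v in variants if v.variant_id in genotypes.columns]
    outcome = estimate_all_snps(cohort, genotypes, ids, stage=stage, by_substudy=by_substudy)
    if gammas_from_cohort:
        expo = exposure_associations(cohort, genotypes, ids)
    else:
        expo = pd.DataFrame(
            {"gamma_hat": [v.gamma_hat for v in variants], "se_gamma": [v.se_gamma for v in variants]},
            index=pd.Index([v.variant_id for v in variants], name="variant_id"),
        ).loc[ids]
    df = expo.join(outcome[["log_hr", "se"]]).reset_index()
    df = df.rename(columns={"log_hr": "big_gamma_hat", "se": "se_big_gamma"})
    return df


def run_mr(
    cohort: pd.DataFrame,
    genotypes: pd.DataFrame,
    variants: list[VariantRecord],
    stage: int = 1,
    methods=_METHODS,
    by_substudy: bool = True,
    gammas_from_cohort: bool = False,
    boot_reps: int = 1000,
    seed: int = 0,
) -> list[est.MRResult]:
    """Per-variant Cox chain plus the pooled estimator battery.

    SNP-exposure effects come from the instrument records (two-sample
    weights) or, with ``gammas_from_cohort``, are re-estimated from the
    cohort itself (one-sample design).
    """
    summary = _summary_frame(cohort, genotypes, variants, stage, by_substudy, gammas_from_cohort)
    ratios = est.wald_ratios(summary)
    results: list[est.MRResult] = []
    ok = summary[
        (summary.gamma_hat != 0)
        & np.isfinite(summary.big_gamma_hat)
        & np.isfinite(summary.se_big_gamma)
    ]
    for method in methods:
        if method == "IVW":
            results.append(est.ivw(ratios))
        elif method == "WM":
            results.append(est.weighted_median(ratios, boot_reps=boot_reps, seed=seed))
        elif method == "PWM":
            results.append(est.penalized_weighted_median(ratios, boot_reps=boot_reps, seed=seed))
        elif method == "Egger":
            # orient to the exposure-raising allele: flip (gamma, Gamma)
            # pairs with negative gamma (the Wald ratio is unchanged)
            sign = np.where(ok.gamma_hat.to_numpy() < 0, -1.0, 1.0)
            slope, intercept = est.mr_egger(
                sign * ok.gamma_hat.to_numpy(),
                sign * ok.big_gamma_hat.to_numpy(),
                ok.se_big_gamma.to_numpy(),
            )
            results.extend([slope, intercept])
        else:
            raise ValueError(f"unknown method {method!r}")
    scale = variants[0].exposure_scale if variants else ""
    return [est.report_hr(r.__class__(**{**r.__dict__, "exposure_scale": scale})) for r in results]


def _results_rows(results, **extra):
    rows = []
    for r in results:
        row = dict(extra)
        row.update(
            method=r.method, exposure_scale=r.exposure_scale,
            n_snps=r.n_instruments, estimate=r.estimate, se=r.se,
            hr=r.hr, hr_low=r.hr_low, hr_high=r.hr_high, p=r.p,
            Q=r.Q, Q_p=r.Q_p, boot_reps=r.boot_reps, seed=r.seed,
        )
        rows.append(row)
    return rows


def run_stratified_mr(
    cohort: pd.DataFrame,
    genotypes: pd.DataFrame,
    variants: list[VariantRecord],
    specs: list[StratumSpec] | None = None,
    stages=(1,),
    methods=_METHODS,
    min_events: int = 10,
    by_substudy: bool = False,
    gammas_from_cohort: bool = False,
    exclude_pleiotropy: bool = False,
    boot_reps: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """One MR battery per (modifier, stratum, stage).

    Strata partition the cohort; individuals missing the modifier are
    excluded and counted.  Strata below ``min_events`` events are
    reported as skipped rather than estimated.  With
    ``exclude_pleiotropy`` the tagged pleiotropic instruments are
    removed before every run.  Benjamini-Hochberg adjustment is applied
    within each (modifier, stage, method) family.
    """
    specs = specs if specs is not None else default_strata()
    if exclude_pleiotropy:
        variants = exclude_pleiotropic(variants)
    rows = []
    for spec in specs:
        labels = assign_strata(cohort, spec)
        n_missing = int(labels.isna().sum())
        for label in spec.labels:
            sub_idx = cohort.index[labels == label]
            sub = cohort.loc[sub_idx]
            if len(sub) == 0:
                continue
            events = int(sub["event"].sum())
            for stage in stages:
                if events < min_events:
                    logger.info("stratified: %s=%s skipped (%d events < %d)", spec.variable, label, events, min_events)
                    rows.append(
                        dict(modifier=spec.variable, stratum=label, stage=stage, method="skipped",
                             n=len(sub), events=events, n_missing_modifier=n_missing, skipped=True)
                    )
                    continue
                results = run_mr(
                    sub, genotypes.loc[sub_idx], variants, stage=stage, methods=methods,
                    by_substudy=by_substudy, gammas_from_cohort=gammas_from_cohort,
                    boot_reps=boot_reps, seed=seed,
                )
                rows.extend(
                    _results_rows(
                        results, modifier=spec.variable, stratum=label, stage=stage,
                        n=len(sub), events=events, n_missing_modifier=n_missing,
                        pleiotropy_excluded=exclude_pleiotropy, skipped=False,
                    )
                )
    table = pd.DataFrame(rows)
    if not table.empty and "p" in table:
        table["p_bh"] = np.nan
        fam = table[~table.get("skipped", False).astype(bool)]
        for (_, _, _), idx in fam.groupby(["modifier", "stage", "method"]).groups.items():
            vals = table.loc[idx, "p"].to_numpy(float)
            mask = np.isfinite(vals)
            if mask.any():
                adj = np.full(vals.shape, np.nan)
                adj[mask] = bh_adjust(vals[mask])
                table.loc[idx, "p_bh"] = adj
    return table


def subtype_analysis(
    cohort: pd.DataFrame,
    genotypes: pd.DataFrame,
    variants: list[VariantRecord],
    subtype: str,
    stage: int = 1,
    methods=_METHODS,
    by_substudy: bool = False,
    gammas_from_cohort: bool = False,
    boot_reps: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Cause-specific MR for one tumour subtype.

    ``subtype`` is e.g. ``"erpr_positive"``, ``"her2_negative"``.
    Events of the target subtype remain events; events of any other
    subtype are censored at their diagnosis time; the standard per-SNP
    Cox + MR chain then runs on the recoded cohort.
    """
    col, _, level = subtype.rpartition("_")
    col = f"{col}_status"
    if col not in cohort.columns:
        raise ValueError(f"unknown subtype column for {subtype!r}")
    target = (cohort["event"] == 1) & (cohort[col].astype("string") == level)
    if target.sum() == 0:
        raise NoEventsError(f"no events of subtype {subtype}")
    recoded = cohort.copy()
    recoded["event"] = target.astype(int)  # other-subtype events censored at diagnosis
    results = run_mr(
        recoded, genotypes, variants, stage=stage, methods=methods,
        by_substudy=by_substudy, gammas_from_cohort=gammas_from_cohort,
        boot_reps=boot_reps, seed=seed,
    )
    return pd.DataFrame(
        _results_rows(results, subtype=subtype, stage=stage, n=len(recoded), events=int(target.sum()))
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min_{j >= i} p_(j) * m / j, capped at 1, returned in the
    original order.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def render_results(table: pd.DataFrame, tsv_path, manifest_path=None, manifest_extra=None) -> None:
    """Write the tidy results table as TSV plus a JSON run manifest.

    The manifest records the seeds used by every stochastic estimator
    row so a run can be reproduced exactly.
    """
    out = table.copy()
    out.to_csv(tsv_path, sep="\t", index=False)
    if manifest_path is not None:
        seeds = sorted({int(s) for s in out.get("seed", pd.Series(dtype=float)).dropna().unique()})
        manifest = {
            "rows": int(len(out)),
            "methods": sorted(out["method"].astype(str).unique()) if "method" in out else [],
            "seeds": seeds,
        }
        if manifest_extra:
            manifest.update(manifest_extra)
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
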