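"""Effect-modifier stratum definitions.

Lifestyle strata used throughout the stratified analyses: obesity-related
cutoffs (BMI, waist-to-hip ratio, physical activity, saturated-fat intake),
behavioural cutoffs (depressive-symptom score, smoking, alcohol), family
history, and exogenous-hormone exposure durations binned in 5-year
intervals.  The same specs drive both the cohort simulator (so an effect
modification can be planted in a named stratum) and the stratified MR
pipeline (so the analysis cuts the cohort along identical lines).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StratumSpec", "default_strata", "assign_strata"]


@dataclass(frozen=True)
class StratumSpec:
    """How one covariate is cut into strata.

    Parameters
    ----------
    variable : str
        Column name in the cohort table.
    kind : str
        ``"binary-cut"`` (single threshold), ``"duration-bins"``
        (non-use plus half-open year bins) or ``"category"``.
    cutoffs : tuple of float
        Strictly increasing thresholds.  For ``binary-cut`` exactly one.
    labels : tuple of str
        Stratum labels, one more than ``cutoffs`` for numeric kinds
        (plus one extra "non-use" label for duration bins).
    side : str
        For ``binary-cut``: ``"ge"`` if the upper stratum is
        ``x >= cutoff`` (e.g. BMI >= 30) or ``"gt"`` for ``x > cutoff``
        (e.g. WHR > 0.85).
    """

    variable: str
    kind: str
    cutoffs: tuple = ()
    labels: tuple = ()
    side: str = "ge"

    def __post_init__(self):
        if self.kind not in {"binary-cut", "duration-bins", "category"}:
            raise ValueError(f"unknown stratum kind {self.kind!r}")
        if list(self.cutoffs) != sorted(set(self.cutoffs)):
            raise ValueError("cutoffs must be strictly increasing")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("stratum labels must be unique")


def default_strata() -> list[StratumSpec]:
    """The default effect-modifier set.

    Cutoffs follow the obesity / lifestyle guideline values used in the
    postmenopausal-cohort analyses this package reimplements: BMI 30 kg/m2,
    WHR 0.85, physical activity 10 MET-hours/week, 9% of calories from
    saturated fat, 0.06 on the CES-D depressive-symptom scale, 15
    cigarettes/day, 14 g alcohol/day (one drink), family history yes/no,
    estrogen-only and estrogen+progestin use in 5-year bins up to 15+
    years, and oral-contraceptive use split at its 5-year median.
    """
    five_year = ("non-use", "<5", "5-<10", "10-<15", ">=15")
    return [
        StratumSpec("bmi", "binary-cut", (30.0,), ("<30", ">=30"), "ge"),
        StratumSpec("whr", "binary-cut", (0.85,), ("<=0.85", ">0.85"), "gt"),
        StratumSpec("met_hours_week", "binary-cut", (10.0,), ("<10", ">=10"), "ge"),
        StratumSpec("sfa_pct_calories", "binary-cut", (9.0,), ("<9", ">=9"), "ge"),
        StratumSpec("cesd_score", "binary-cut", (0.06,), ("<0.06", ">=0.06"), "ge"),
        StratumSpec("cigarettes_per_day", "binary-cut", (15.0,), ("<15", ">=15"), "ge"),
        StratumSpec("alcohol_g_day", "binary-cut", (14.0,), ("<14", ">=14"), "ge"),
        StratumSpec("family_history", "category", (), ("no", "yes")),
        StratumSpec("e_only_years", "duration-bins", (5.0, 10.0, 15.0), five_year),
        StratumSpec("ep_years", "duration-bins", (5.0, 10.0, 15.0), five_year),
        StratumSpec("oc_years", "duration-bins", (5.0,), ("non-use", "<5", ">=5")),
    ]


def assign_strata(cohort: pd.DataFrame, spec: StratumSpec) -> pd.Series:
    """Label every individual with their stratum for one modifier.

    Missing modifier values map to NaN (excluded, counted by callers).
    Duration bins are half-open ``[a, b)`` with exact zero meaning
    non-use; binary categories 0/1 map to the spec's two labels.
    """
    x = cohort[spec.variable]
    out = pd.Series(pd.NA, index=cohort.index, dtype="object")
    valid = x.notna()
    if spec.kind == "binary-cut":
        (cut,) = spec.cutoffs
        lo, hi = spec.labels
        above = (x > cut) if spec.side == "gt" else (x >= cut)
        out[valid & above] = hi
        out[valid & ~above] = lo
    elif spec.kind == "duration-bins":
        # exact zero is non-use; positive durations fall in half-open [a, b)
        out[valid & (x == 0)] = spec.labels[0]
        pos = valid & (x > 0)
        edges = [0.0, *spec.cutoffs, np.inf]
        for lab, lo_e, hi_e in zip(spec.labels[1:], edges[:-1], edges[1:]):
            out[pos & (x >= lo_e) & (x < hi_e)] = lab
    else:  # category
        no, yes = spec.labels
        out[valid & (x.astype(float) == 0)] = no
        out[valid & (x.astype(float) != 0)] = yes
    return out
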