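"""Cohort tables and one-way ANOVA comparisons.

Per-patient overall tortuosity values (one per vessel class, on the
x1e4 table scale) are the independent inputs.  Two comparisons are
run for each vessel class, mirroring the study design for diabetic
retinopathy (DR):

* genesis — non-DR group versus the pooled DR group (V1+V2+V3);
* progression — across severity groups V1, V2, V3.

Each row reports group means +- sample SD (n-1 denominator), the mean
difference (DR - nonDR, or V3 - V1), the one-way ANOVA F and p, and a
significance flag at p < 0.05.  No covariate adjustment and no
multiple-testing correction are applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GROUPS, REPORT_CLASSES

DR_GROUPS = ("V1", "V2", "V3")
ALPHA = 0.05


@dataclass
class ANOVAResult:
    F: float
    df_between: int
    df_within: int
    p: float
    valid: bool = True

    @property
    def significant(self) -> bool:
        return self.valid and self.p < ALPHA


@dataclass
class PatientRecord:
    """One patient's per-class tortuosity on the table (x1e4) scale."""

    patient_id: str
    group: str
    tau: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


@dataclass
class CohortTable:
    """The two comparison tables plus per-class exclusion counts."""

    genesis: pd.DataFrame  # nonDR vs pooled DR
    severity: pd.DataFrame  # V1 vs V2 vs V3
    n_excluded: dict[str, int] = field(default_factory=dict)


def anova_oneway(groups: list[np.ndarray]) -> ANOVAResult:
    """Standard one-way ANOVA via the between/within decomposition.

    Degenerate input (zero variance both between and within groups)
    leaves F undefined and is flagged invalid rather than zero-filled.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    N = sum(len(g) for g in groups)
    k = len(groups)
    allv = np.concatenate(groups)
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    ss_between = sum(len(g) * (g.mean() - allv.mean()) ** 2 for g in groups)
    if ss_within == 0 and ss_between == 0:
        return ANOVAResult(np.nan, k - 1, N - k, np.nan, valid=False)
    F, p = sps.f_oneway(*groups)
    if not np.isfinite(F):  # zero within-group variance, nonzero between
        return ANOVAResult(np.inf, k - 1, N - k, 0.0, valid=True)
    return ANOVAResult(float(F), k - 1, N - k, float(p), valid=True)


def group_difference(mean_ref: float, mean_cmp: float) -> float:
    """Mean difference column: comparison minus reference group."""
    if not (np.isfinite(mean_ref) and np.isfinite(mean_cmp)):
        raise ValueError("difference requires both group means")
    return float(mean_cmp) - float(mean_ref)


def _class_values(records: list[PatientRecord], cls: str, groups) -> dict[str, np.ndarray]:
    out = {}
    for g in groups:
        vals = [
            r.tau.get(cls)
            for r in records
            if r.group == g and r.tau.get(cls) is not None and np.isfinite(r.tau.get(cls))
        ]
        out[g] = np.array(vals, float)
    return out


def summarize_cohort(records: list[PatientRecord]) -> CohortTable:
    """Both comparison tables from per-patient records.

    Patients with a missing tau in a class are excluded from that
    class's rows only (per-class listwise exclusion); the exclusion
    count is reported.
    """
    present = {r.group for r in records}
    missing = [g for g in GROUPS if g not in present]
    if missing:
        raise ValueError(f"cohort is missing groups: {missing}")

    n_excluded: dict[str, int] = {}
    genesis_rows, severity_rows = [], []
    for cls in REPORT_CLASSES:
        vals = _class_values(records, cls, GROUPS)
        n_total = len(records)
        n_used = sum(len(v) for v in vals.values())
        n_excluded[cls] = n_total - n_used

        dr = np.concatenate([vals[g] for g in DR_GROUPS])
        nondr = vals["nonDR"]
        if len(nondr) >= 2 and len(dr) >= 2:
            a = anova_oneway([nondr, dr])
            genesis_rows.append(
                {
                    "vessel_class": cls,
                    "mean_nonDR": nondr.mean(),
                    "sd_nonDR": nondr.std(ddof=1),
                    "n_nonDR": len(nondr),
                    "mean_DR": dr.mean(),
                    "sd_DR": dr.std(ddof=1),
                    "n_DR": len(dr),
                    "difference": group_difference(nondr.mean(), dr.mean()),
                    "F": a.F,
                    "p": a.p,
                    "significant": a.significant,
                }
            )
        if all(len(vals[g]) >= 2 for g in DR_GROUPS):
            a = anova_oneway([vals[g] for g in DR_GROUPS])
            row = {"vessel_class": cls}
            for g in DR_GROUPS:
                row[f"mean_{g}"] = vals[g].mean()
                row[f"sd_{g}"] = vals[g].std(ddof=1)
                row[f"n_{g}"] = len(vals[g])
            row["difference"] = group_difference(vals["V1"].mean(), vals["V3"].mean())
            row["F"], row["p"], row["significant"] = a.F, a.p, a.significant
            severity_rows.append(row)

    return CohortTable(
        genesis=pd.DataFrame(genesis_rows),
        severity=pd.DataFrame(severity_rows),
        n_excluded=n_excluded,
    )
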