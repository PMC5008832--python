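"""Validation statistics: relative qPCR quantification and clinical tests.

Relative expression follows the 2^-ddCt construction: replicate Ct values
are averaged first, the calibrator gene's Ct is subtracted per patient and
timepoint (dCt), the control group's mean dCt is subtracted (ddCt), and the
fold change is 2^-ddCt.  Standard dilution curves regress Ct on log10 input
mass; amplification efficiency is 10^(-1/slope) - 1.  Group comparisons use
the Wilcoxon rank-sum test (exact by enumeration in the small-sample,
tie-free regime) and Pearson's chi-squared test for ordinal staining scores.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from beprog.types import (
    ClinicalRecord,
    ContingencyTable,
    CtTable,
    StandardCurve,
    ValidationError,
)

# the dilution series used for the standard curves, in ng of input RNA
DILUTION_SERIES_NG = (100.0, 10.0, 1.0, 0.1, 0.01, 0.001, 0.0001)

CLINICAL_MARKERS = ("qpcr_cyr61", "qpcr_taz", "ihc_cyr61", "ihc_taz")


def delta_delta_ct(
    ct: CtTable, target: str, control_group: str = "nonP-BE"
) -> pd.DataFrame:
    """Per-patient 2^-ddCt fold changes of ``target`` against the calibrator.

    Duplicate Ct values are averaged before any subtraction.  The ddCt
    baseline is the control group's mean dCt within the same timepoint.
    Returns a frame (patient_id, group, timepoint, delta_ct, delta_delta_ct,
    fold_change).
    """
    rows = ct.rows
    if target not in set(rows["gene_id"]):
        raise ValidationError(f"target gene {target!r} absent from the Ct table")
    means = (
        rows.groupby(["patient_id", "group", "timepoint", "gene_id"])["ct"]
        .mean()
        .reset_index()
    )
    tgt = means[means["gene_id"] == target]
    cal = means[means["gene_id"] == ct.calibrator_gene].set_index(
        ["patient_id", "timepoint"]
    )["ct"]
    out = []
    for _, row in tgt.iterrows():
        key = (row["patient_id"], row["timepoint"])
        if key not in cal.index:
            raise ValidationError(
                f"missing calibrator {ct.calibrator_gene!r} measurement for "
                f"patient {row['patient_id']!r} at {row['timepoint']!r}"
            )
        out.append(
            {
                "patient_id": row["patient_id"],
                "group": row["group"],
                "timepoint": row["timepoint"],
                "delta_ct": row["ct"] - cal.loc[key],
            }
        )
    df = pd.DataFrame(out)
    if not (df["group"] == control_group).any():
        raise ValidationError(f"no patients in control group {control_group!r}")
    baseline = (
        df[df["group"] == control_group].groupby("timepoint")["delta_ct"].mean()
    )
    df["delta_delta_ct"] = df["delta_ct"] - df["timepoint"].map(baseline)
    df["fold_change"] = 2.0 ** (-df["delta_delta_ct"])
    return df


def fold_change_summary(fold_changes: pd.Series) -> dict:
    """Geometric (primary, ratios multiply) and arithmetic mean fold change."""
    fc = np.asarray(fold_changes, dtype=float)
    return {
        "geometric_mean": float(np.exp(np.mean(np.log(fc)))),
        "arithmetic_mean": float(np.mean(fc)),
        "n": int(fc.size),
    }


def fit_standard_curve(input_ng, ct) -> StandardCurve:
    """Least-squares standard curve of Ct on log10(input mass in ng)."""
    x = np.asarray(input_ng, dtype=float)
    y = np.asarray(ct, dtype=float)
    if np.any(x <= 0):
        raise ValidationError("input masses must be positive")
    if len(set(x)) < 3:
        raise ValidationError("need >= 3 distinct dilution points")
    if x.shape != y.shape:
        raise ValidationError("input_ng and ct must have equal length")
    res = stats.linregress(np.log10(x), y)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(min(res.rvalue**2, 1.0)),
    )


def _exact_u_sf_cdf(n: int, m: int) -> np.ndarray:
    """Null counts of the Mann-Whitney U statistic for samples of size n, m."""
    counts = np.zeros((n + 1, m + 1, n * m + 1))
    counts[0, :, 0] = 1.0
    counts[:, 0, 0] = 1.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            upper = i * j
            c = counts[i, j - 1, : upper + 1].copy()
            shifted = np.zeros(upper + 1)
            shifted[j:] = counts[i - 1, j, : upper + 1 - j]
            counts[i, j, : upper + 1] = c + shifted
    return counts[n, m]


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (U, p) with U the number of (x, y) pairs where x exceeds y (the
    convention of R's wilcox.test).  The null distribution is enumerated
    exactly when n + m <= 20 and there are no ties; otherwise the normal
    approximation with continuity and tie correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    rank_sum_x = float(ranks[:n].sum())
    u = rank_sum_x - n * (n + 1) / 2.0
    has_ties = np.unique(combined).size != combined.size

    if n + m <= 20 and not has_ties:
        pmf = _exact_u_sf_cdf(n, m)
        total = pmf.sum()
        ui = int(round(u))
        lower = pmf[: ui + 1].sum() / total
        upper = pmf[ui:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        return u, float(p)

    mu = n * m / 2.0
    N = n + m
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (N * (N - 1)))
    sigma_sq = n * m / 12.0 * ((N + 1) - tie_term)
    if sigma_sq <= 0:
        return u, 1.0
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma_sq)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * stats.norm.sf(z))
    return u, float(p)


def chi_squared(
    t: ContingencyTable, correction: bool = True
) -> tuple[float, int, float]:
    """Pearson's chi-squared test of independence on a group x score table.

    Yates continuity correction applies (by default) to 2x2 tables only.
    """
    counts = t.counts.to_numpy()
    if np.any(counts.sum(axis=1) == 0) or np.any(counts.sum(axis=0) == 0):
        raise ValidationError("a row or column of the table sums to zero")
    res = stats.chi2_contingency(counts, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def summarize_followup(
    records: list[ClinicalRecord], group: str | None = None
) -> dict:
    """Per-group mean (1 decimal), min and max of follow-up years.

    With ``group`` given, that single group's summary; otherwise a dict per
    group present.
    """
    if group is not None:
        years = [r.years_fup for r in records if r.group == group]
        if not years:
            raise ValidationError(f"no records in group {group!r}")
        return {
            "group": group,
            "n": len(years),
            "mean": round(float(np.mean(years)), 1),
            "min": int(min(years)),
            "max": int(max(years)),
        }
    groups = sorted({r.group for r in records})
    return {g: summarize_followup(records, g) for g in groups}


def score_table(
    records: list[ClinicalRecord], marker: str, timepoint: str
) -> ContingencyTable:
    """Group x ordinal-score counts for one marker at one timepoint.

    Zero-count categories of the marker's alphabet are retained as columns.
    """
    from beprog.types import IHC_CYR61_LEVELS, IHC_TAZ_LEVELS, QPCR_LEVELS

    if marker not in CLINICAL_MARKERS:
        raise ValidationError(f"unknown marker {marker!r}, expected {CLINICAL_MARKERS}")
    if timepoint not in ("t0", "t1"):
        raise ValidationError(f"unknown timepoint {timepoint!r}")
    field = f"{marker}_{timepoint}"
    if marker.startswith("qpcr"):
        levels = QPCR_LEVELS
    elif marker == "ihc_cyr61":
        levels = IHC_CYR61_LEVELS
    else:
        levels = IHC_TAZ_LEVELS
    groups = sorted({r.group for r in records})
    counts = pd.DataFrame(0, index=groups, columns=list(levels))
    for r in records:
        counts.loc[r.group, getattr(r, field)] += 1
    return ContingencyTable(counts)
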