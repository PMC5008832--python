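"""Empirical-Bayes moderated differential expression with Lods selection.

Per gene the ordinary pooled two-sample statistics are shrunk toward a
common variance prior whose hyperparameters (d0, s0^2) are estimated by
matching moments of log s_g^2 to its theoretical scaled-F form.  The
selection score is the log posterior odds of differential expression
("Lods" / B-statistic) under an assumed prior proportion of changed genes,
so a fixed Lods cutoff is already a multiplicity-aware rule.  The cutoff
itself is calibrated on a negative-control contrast (two sample sets where
no real differences are expected) via :func:`calibrate_null`.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import special, stats

from beprog.enrichment import bh_adjust
from beprog.types import (
    CandidateSet,
    DEResult,
    EBayesParams,
    ExpressionMatrix,
    ValidationError,
)

LODS_FLOOR = -1e6
_VAR_FLOOR = float(np.finfo(float).eps)
# clip limits for the DE-coefficient variance prior, on the unscaled scale
_V0_LIM = (0.1**2, 4.0**2)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from per-gene sample variances.

    Works on z = log(s2): under the scaled-F model z - digamma(df/2) +
    log(df/2) has mean log(s0^2) - digamma(d0/2) - log(2/d0) and excess
    variance trigamma(d0/2) beyond trigamma(df/2).
    """
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) if e.size > 1 else 0.0
    evar_excess = evar - float(special.polygamma(1, df / 2.0))
    if evar_excess > 0:
        d0 = 2.0 * _trigamma_inverse(evar_excess)
        s0_sq = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        # no dispersion beyond sampling noise: complete pooling onto the
        # common variance (exact when all sample variances coincide)
        d0 = math.inf
        s0_sq = float(np.mean(s2))
    return d0, s0_sq


def _estimate_v0(
    t_mod: np.ndarray, v_unscaled: float, df_total: float, p_de: float
) -> float:
    """Estimate the DE-coefficient variance prior from the top |t| genes.

    The expected proportion of DE genes pins down which tail quantiles the
    largest moderated statistics should occupy if they were null; the excess
    of observed over expected quantile yields a per-gene v0 estimate which
    is averaged after clipping.
    """
    ngenes = t_mod.size
    ntarget = max(1, math.ceil(p_de / 2.0 * ngenes))
    prop = max(ntarget / ngenes, p_de)
    tabs = np.sort(np.abs(t_mod))[::-1][:ntarget]
    v0 = np.zeros(ntarget)
    p0 = 2.0 * stats.t.sf(tabs, df_total)
    r = np.arange(1, ntarget + 1)
    ptarget = ((r - 0.5) / ngenes - (1.0 - prop) * p0) / prop
    pos = ptarget > p0
    if np.any(pos):
        qtarget = stats.t.isf(ptarget[pos] / 2.0, df_total)
        with np.errstate(divide="ignore", invalid="ignore"):
            v0[pos] = v_unscaled * ((tabs[pos] / qtarget) ** 2 - 1.0)
    v0 = np.clip(v0, _V0_LIM[0] * v_unscaled, _V0_LIM[1] * v_unscaled)
    return float(np.mean(v0))


def _lods(
    t_mod: np.ndarray, df_total: float, v_unscaled: float, v0: float, p_de: float
) -> np.ndarray:
    """Log posterior odds of differential expression (B-statistic)."""
    r = (v_unscaled + v0) / v_unscaled
    t2 = t_mod**2
    if math.isinf(df_total):
        kernel = t2 * (1.0 - 1.0 / r) / 2.0
    else:
        kernel = (1.0 + df_total) / 2.0 * np.log((t2 + df_total) / (t2 / r + df_total))
    lods = math.log(p_de / (1.0 - p_de)) - math.log(r) / 2.0 + kernel
    return np.clip(np.nan_to_num(lods, neginf=LODS_FLOOR), LODS_FLOOR, None)


def fit_moderated_values(
    values: pd.DataFrame,
    cols_a: list[str],
    cols_b: list[str],
    p_de: float = 0.01,
) -> tuple[DEResult, EBayesParams]:
    """Moderated two-group fit on raw column sets (group_a minus group_b)."""
    n_a, n_b = len(cols_a), len(cols_b)
    if n_a < 2 or n_b < 2:
        raise ValidationError("each group needs at least 2 samples")
    a = values[cols_a].to_numpy(dtype=float)
    b = values[cols_b].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = mean_a - mean_b
    df_resid = n_a + n_b - 2
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + (
        (b - mean_b[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid
    zero_var = s2 <= _VAR_FLOOR
    if np.all(zero_var):
        raise ValidationError("all genes have zero residual variance")
    s2 = np.where(zero_var, _VAR_FLOOR, s2)

    d0, s0_sq = estimate_prior(s2[~zero_var], df_resid)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = math.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    v_unscaled = 1.0 / n_a + 1.0 / n_b
    se = np.sqrt(s2_post * v_unscaled)
    t_mod = log2fc / se
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p_adj = bh_adjust(p)

    v0 = max(_estimate_v0(t_mod, v_unscaled, df_total, p_de), 1e-8 * v_unscaled)
    lods = _lods(t_mod, df_total, v_unscaled, v0, p_de)

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "mean_expr": values[cols_a + cols_b].mean(axis=1).to_numpy(),
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "p_adj": p_adj,
            "lods": lods,
            "zero_variance": zero_var,
        },
        index=values.index,
    )
    params = EBayesParams(d0=d0, s0_sq=s0_sq, p_de=p_de, v0=v0)
    return DEResult(table, params), params


def fit_moderated(
    m: ExpressionMatrix,
    group_a: str = "P-BE",
    group_b: str = "nonP-BE",
    p_de: float = 0.01,
) -> tuple[DEResult, EBayesParams]:
    """Moderated differential expression between two clinical groups.

    ``log2fc`` is mean(group_a) - mean(group_b), so positive values are
    up-regulated in ``group_a``.
    """
    groups = m.groups()
    cols_a = [s for s in m.sample_ids if groups[s] == group_a]
    cols_b = [s for s in m.sample_ids if groups[s] == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValidationError(
            f"need >= 2 samples per group, got {len(cols_a)} {group_a!r} "
            f"and {len(cols_b)} {group_b!r}"
        )
    return fit_moderated_values(m.values, cols_a, cols_b, p_de=p_de)


def select_candidates(
    de: DEResult,
    lods_min: float = 5.0,
    abs_log2fc_min: float = 0.58,
    up_only: bool = False,
) -> CandidateSet:
    """Threshold the DE table: lods >= lods_min AND |log2fc| >= abs_log2fc_min.

    Both bounds inclusive.  Candidates are ordered by descending lods, ties
    broken by gene id.  With ``up_only`` only positive fold changes pass.
    """
    if not (np.isfinite(lods_min) and np.isfinite(abs_log2fc_min)):
        raise ValidationError("thresholds must be finite")
    t = de.table
    fc_ok = (
        t["log2fc"] >= abs_log2fc_min
        if up_only
        else t["log2fc"].abs() >= abs_log2fc_min
    )
    sel = t[(t["lods"] >= lods_min) & fc_ok]
    # descending lods, ascending gene id on ties
    order = sorted(sel.index, key=lambda g: (-sel.at[g, "lods"], g))
    return CandidateSet(genes=list(order), provenance={g: ("DE",) for g in order})


def calibrate_null(
    m_a: ExpressionMatrix,
    m_b: ExpressionMatrix,
    lods_min: float = 5.0,
    p_de: float = 0.01,
) -> dict:
    """Negative-control calibration of the Lods cutoff.

    Runs the moderated fit treating dataset-of-origin as the contrast on two
    sample sets where no real differences are expected; a threshold passes
    calibration when no gene reaches it.
    """
    if set(m_a.gene_ids) != set(m_b.gene_ids):
        raise ValidationError("calibration inputs must share one gene set")
    genes = list(m_a.gene_ids)
    values = pd.concat([m_a.values.loc[genes], m_b.values.loc[genes]], axis=1)
    de, _ = fit_moderated_values(
        values, list(m_a.sample_ids), list(m_b.sample_ids), p_de=p_de
    )
    lods = de.table["lods"]
    return {
        "n_above": int((lods >= lods_min).sum()),
        "max_lods": float(lods.max()),
        "lods_min": float(lods_min),
    }
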