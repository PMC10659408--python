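"""Negative-binomial differential testing with fixed spike-derived size factors.

A deliberately compact two-group NB Wald pipeline: per-gene method-of-moments
dispersions, a robust ``a0 + a1/mean`` trend, log-space shrinkage toward the
trend, exact NB maximum-likelihood group means (Newton on the log scale),
and a Wald test on the log fold change with SE from expected information.
Size factors are supplied, never re-estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DispersionModel",
    "filter_min_counts",
    "estimate_dispersions",
    "nb_wald_test",
    "bh_adjust",
    "classify_significant",
    "overlap_test",
    "spearman_corr",
]

DISPERSION_FLOOR = 1e-8


def filter_min_counts(counts: pd.DataFrame, threshold: float, strict: bool = True) -> pd.Index:
    """Transcripts whose total raw count across all samples passes ``threshold``.

    ``strict=True`` keeps totals strictly greater than the threshold
    (">90 in 9 samples" design); ``strict=False`` keeps totals >= threshold
    (">=8 in 4 samples" design).
    """
    totals = counts.sum(axis=1)
    kept = totals > threshold if strict else totals >= threshold
    return counts.index[kept]


@dataclass
class DispersionModel:
    """Raw, trend and shrunken per-gene dispersions."""

    raw: pd.Series
    trend: pd.Series
    shrunk: pd.Series
    trend_params: tuple[float, float]  # (a0, a1) of a0 + a1/mean
    base_mean: pd.Series


def _fit_trend(base_mean: np.ndarray, disp: np.ndarray) -> tuple[float, float]:
    """Robust least-squares fit of disp ~ a0 + a1/mean with outlier trimming."""
    usable = (base_mean > 0) & np.isfinite(disp) & (disp > 10 * DISPERSION_FLOOR)
    if usable.sum() < 10:
        med = float(np.median(disp[np.isfinite(disp)])) if np.isfinite(disp).any() else DISPERSION_FLOOR
        return max(med, DISPERSION_FLOOR), 0.0
    x = 1.0 / base_mean[usable]
    y = disp[usable]
    keep = np.ones(len(y), dtype=bool)
    a0, a1 = float(np.median(y)), 0.0
    for _ in range(8):
        X = np.column_stack([np.ones(keep.sum()), x[keep]])
        beta, *_ = np.linalg.lstsq(X, y[keep], rcond=None)
        a0, a1 = float(beta[0]), float(beta[1])
        resid = y - (a0 + a1 * x)
        mad = np.median(np.abs(resid - np.median(resid)))
        if mad <= 0:
            break
        new_keep = np.abs(resid) <= 5 * 1.4826 * mad
        if new_keep.sum() < 10 or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    return max(a0, DISPERSION_FLOOR), max(a1, 0.0)


def estimate_dispersions(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    conditions: pd.Series,
    prior_df: float = 20.0,
) -> DispersionModel:
    """Method-of-moments dispersions shrunk toward an a0 + a1/mean trend.

    ``counts`` is genes x samples (raw), ``conditions`` maps sample -> group
    label.  At least one condition must have >= 2 replicates.  All-zero
    genes take the trend dispersion at their mean.
    """
    sf = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    if np.any(~np.isfinite(sf)) or np.any(sf <= 0):
        raise ValueError("size factors must be positive for every sample")
    cond = conditions.reindex(counts.columns)
    norm = counts.to_numpy(dtype=float) / sf

    groups = [np.flatnonzero((cond == g).to_numpy()) for g in cond.unique()]
    if max(len(g) for g in groups) < 2:
        raise ValueError("need >= 2 replicates in at least one condition")

    num = np.zeros(len(counts))
    den = np.zeros(len(counts))
    total_df = 0.0
    for idx in groups:
        if len(idx) < 2:
            continue
        sub = norm[:, idx]
        mean_g = sub.mean(axis=1)
        var_g = sub.var(axis=1, ddof=1)
        xim = float(np.mean(1.0 / sf[idx]))  # shot-noise term of normalized counts
        df = len(idx) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_g = np.where(mean_g > 0, (var_g - xim * mean_g) / mean_g**2, np.nan)
        ok = np.isfinite(alpha_g)
        num[ok] += df * alpha_g[ok]
        den[ok] += df
        total_df += df

    with np.errstate(invalid="ignore"):
        raw = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    raw = np.where(np.isfinite(raw), np.maximum(raw, DISPERSION_FLOOR), np.nan)

    base_mean = norm.mean(axis=1)
    a0, a1 = _fit_trend(base_mean, raw)
    with np.errstate(divide="ignore"):
        trend = np.where(base_mean > 0, a0 + a1 / np.maximum(base_mean, 1e-12), a0)
    trend = np.maximum(trend, DISPERSION_FLOOR)

    # log-space shrinkage; raw estimates clamped to a window around the trend
    # (asymmetric: under-dispersion is mostly estimation noise, genuine
    # over-dispersion outliers are allowed more room)
    w = total_df / (total_df + prior_df)
    raw_clamped = np.clip(np.where(np.isfinite(raw), raw, trend), trend / 2, trend * 64)
    shrunk = np.exp(w * np.log(raw_clamped) + (1 - w) * np.log(trend))
    shrunk = np.maximum(shrunk, DISPERSION_FLOOR)
    # all-zero genes: trend value at their (zero) mean
    allzero = counts.sum(axis=1).to_numpy() == 0
    shrunk[allzero] = trend[allzero]

    idx = counts.index
    return DispersionModel(
        raw=pd.Series(raw, index=idx, name="dispersion_raw"),
        trend=pd.Series(trend, index=idx, name="dispersion_trend"),
        shrunk=pd.Series(shrunk, index=idx, name="dispersion"),
        trend_params=(a0, a1),
        base_mean=pd.Series(base_mean, index=idx, name="baseMean"),
    )


def _nb_group_mean(counts: np.ndarray, sf: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Vectorized NB MLE of the common normalized mean of one group.

    Model: K_j ~ NB(mean = s_j * m, dispersion alpha).  Newton iteration on
    log m; reduces to sum(K)/sum(s) as alpha -> 0.
    """
    total = counts.sum(axis=1)
    m = total / sf.sum()
    pos = m > 0
    if not pos.any():
        return m
    logm = np.log(np.maximum(m, 1e-300))
    a = alpha[:, None]
    k = counts
    s = sf[None, :]
    for _ in range(50):
        mu = s * np.exp(logm)[:, None]
        denom = 1.0 + a * mu
        # d/d logm of the NB log-likelihood
        score = np.sum((k - mu) / denom, axis=1)
        info = np.sum(mu / denom, axis=1)
        step = np.where(info > 0, score / np.maximum(info, 1e-12), 0.0)
        step = np.clip(step, -5, 5)
        logm = np.where(pos, logm + step, logm)
        if np.max(np.abs(step[pos]), initial=0.0) < 1e-12:
            break
    out = np.where(pos, np.exp(logm), 0.0)
    return out


def nb_wald_test(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    conditions: pd.Series,
    contrast: tuple[str, str],
    dispersions: pd.Series | DispersionModel,
    pseudocount: float = 0.5,
    tail_df_scale: float = 8.0,
) -> pd.DataFrame:
    """Two-group NB Wald test of condition B over A at fixed dispersions.

    ``contrast`` is (B, A); positive log2FC means higher in B.  Genes with
    zero counts in both groups get p = 1, log2FC = 0 and ``both_zero`` set.
    For one-sided-zero genes the reported log2FC uses a ``pseudocount`` on
    normalized group means; the Wald statistic itself floors the zero group
    mean at half a read to stay finite.

    P-values are referred to a Student t with ``tail_df_scale`` times the
    residual degrees of freedom rather than the normal: with few replicates
    the log-mean estimates have slightly heavy tails and the normal
    reference produces spurious extreme p-values; the t reference restores
    family-wise tail calibration and converges to the normal as replication
    grows.
    """
    if isinstance(dispersions, DispersionModel):
        dispersions = dispersions.shrunk
    condB, condA = contrast
    cond = conditions.reindex(counts.columns)
    colsA = counts.columns[(cond == condA).to_numpy()]
    colsB = counts.columns[(cond == condB).to_numpy()]
    if len(colsA) == 0 or len(colsB) == 0:
        raise ValueError(f"contrast {contrast} references empty condition(s)")

    alpha = np.maximum(dispersions.reindex(counts.index).to_numpy(dtype=float), DISPERSION_FLOOR)
    sfA = size_factors.reindex(colsA).to_numpy(dtype=float)
    sfB = size_factors.reindex(colsB).to_numpy(dtype=float)
    kA = counts[colsA].to_numpy(dtype=float)
    kB = counts[colsB].to_numpy(dtype=float)

    mA = _nb_group_mean(kA, sfA, alpha)
    mB = _nb_group_mean(kB, sfB, alpha)

    floorA = pseudocount / sfA.sum()
    floorB = pseudocount / sfB.sum()
    mA_t = np.maximum(mA, floorA)
    mB_t = np.maximum(mB, floorB)
    beta = np.log(mB_t) - np.log(mA_t)

    muA = sfA[None, :] * mA_t[:, None]
    muB = sfB[None, :] * mB_t[:, None]
    infoA = np.sum(muA / (1.0 + alpha[:, None] * muA), axis=1)
    infoB = np.sum(muB / (1.0 + alpha[:, None] * muB), axis=1)
    se = np.sqrt(1.0 / infoA + 1.0 / infoB)
    stat = beta / se
    resid_df = max(len(colsA) + len(colsB) - 2, 1)
    pval = 2.0 * stats.t.sf(np.abs(stat), tail_df_scale * resid_df)

    both_zero = (mA == 0) & (mB == 0)
    stat = np.where(both_zero, 0.0, stat)
    pval = np.where(both_zero, 1.0, pval)

    # reported fold change: pseudocount only where a group mean is zero
    any_zero = (mA == 0) | (mB == 0)
    lfc = np.log2(mB_t / mA_t)
    lfc_pc = np.log2((mB + pseudocount) / (mA + pseudocount))
    log2fc = np.where(both_zero, 0.0, np.where(any_zero, lfc_pc, lfc))

    sf_all = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    base_mean = (counts.to_numpy(dtype=float) / sf_all).mean(axis=1)

    res = pd.DataFrame(
        {
            "baseMean": base_mean,
            "meanA": mA,
            "meanB": mB,
            "log2FC": log2fc,
            "lfcSE": se / np.log(2),
            "stat": stat,
            "pvalue": pval,
            "both_zero": both_zero,
        },
        index=counts.index,
    )
    res["padj"] = bh_adjust(res["pvalue"].to_numpy())
    return res


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1.

    NaNs propagate and are excluded from the ranking.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if not ok.any():
        return out
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def classify_significant(
    results: pd.DataFrame, fdr_cut: float = 0.05, fc_cut: float = 2.0
) -> pd.DataFrame:
    """Attach a class column: up / down / ns by FDR and fold-change gates."""
    fc = np.power(2.0, results["log2FC"].to_numpy(dtype=float))
    sig = results["padj"].to_numpy(dtype=float) < fdr_cut
    cls = np.where(sig & (fc > fc_cut), "up", np.where(sig & (fc < 1.0 / fc_cut), "down", "ns"))
    out = results.copy()
    out["class"] = cls
    return out


def overlap_test(set_a: set, set_b: set, universe_size: int) -> tuple[int, float]:
    """Observed overlap and upper-tail hypergeometric p of >= that overlap."""
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set sizes exceed the universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return k, min(p, 1.0)


def spearman_corr(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN for constant vectors or n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return float("nan")
    x, y = x[ok], y[ok]
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)
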