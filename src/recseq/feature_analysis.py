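"""Per-transcript covariates, equal-size binning and reciprocity classifiers.

Structure-score ("PARS-like") summaries over 5'UTR and early-CDS windows,
start-codon context scoring by position-weight geometric means, equal-size
feature binning, and the reciprocal mRPF/iRPF (leaky scanning) and
uRPF/mRPF (upstream initiation) classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import Annotations, TranscriptAnnotation

__all__ = [
    "PARS_SUMMARY_COLUMNS",
    "compute_pars_summaries",
    "pars_summary_table",
    "ContextScoreModel",
    "compute_context_score",
    "bin_equal_size",
    "summarize_bins",
    "classify_leaky_scanning",
    "classify_uaug_reciprocity",
    "rro_by_context",
    "rank_heatmap_table",
]

PARS_SUMMARY_COLUMNS = ["total_pars", "max30_pars", "start30_pars", "plus15_pars", "plus30_pars", "plus45_pars"]


def _window_sum(scores: np.ndarray, start: int, end: int) -> float:
    """Sum of scores over 1-based inclusive transcript positions [start, end]."""
    return float(scores[start - 1 : end].sum())


def compute_pars_summaries(
    scores: np.ndarray,
    annot: TranscriptAnnotation,
    window: int = 30,
    plus_offsets: tuple[int, ...] = (15, 30, 45),
    truncate_short_utr: bool = True,
) -> dict[str, float]:
    """Structure-score summaries for one transcript.

    ``scores`` is the per-nucleotide profile over the whole transcript
    (index 0 = position 1).  Returns total (5'UTR sum), max30 (best
    ``window``-nt sum in the 5'UTR; the full-UTR sum for 5'UTRs shorter
    than the window when ``truncate_short_utr``), start30 (the ``window``
    nt centred on the mAUG, defined only for utr5_len >= window//2) and
    30-nt sums starting at signed positions +15/+30/+45 downstream of the
    mAUG.  Undefined summaries are NaN.
    """
    if len(scores) < annot.tx_len:
        raise ValueError(f"{annot.transcript_id}: profile shorter than transcript")
    scores = np.asarray(scores, dtype=float)
    utr = scores[: annot.utr5_len]
    out: dict[str, float] = {}
    out["total_pars"] = float(utr.sum())

    n = annot.utr5_len
    if n == 0:
        out["max30_pars"] = 0.0
    elif n < window:
        out["max30_pars"] = float(utr.sum()) if truncate_short_utr else float("nan")
    else:
        csum = np.concatenate([[0.0], np.cumsum(utr)])
        out["max30_pars"] = float((csum[window:] - csum[:-window]).max())

    half = window // 2
    if n >= half and annot.cds_start + half - 1 <= annot.tx_len:
        out["start30_pars"] = _window_sum(scores, annot.cds_start - half, annot.cds_start + half - 1)
    else:
        out["start30_pars"] = float("nan")

    for off in plus_offsets:
        start = annot.cds_start + off - 1  # signed +off -> transcript coordinate
        end = start + window - 1
        key = f"plus{off}_pars"
        out[key] = _window_sum(scores, start, end) if end <= annot.tx_len else float("nan")
    return out


def pars_summary_table(profiles: pd.DataFrame, annots: Annotations, **kwargs) -> pd.DataFrame:
    """Summaries for all transcripts with a profile.

    ``profiles`` has columns ``transcript_id, position, score``; transcripts
    without a profile are simply absent from the result.
    """
    rows = {}
    for tx, grp in profiles.groupby("transcript_id"):
        if tx not in annots:
            continue
        a = annots[tx]
        scores = np.zeros(a.tx_len)
        pos = grp["position"].to_numpy(dtype=int)
        scores[pos - 1] = grp["score"].to_numpy(dtype=float)
        rows[tx] = compute_pars_summaries(scores, a, **kwargs)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=PARS_SUMMARY_COLUMNS)
    df.index.name = "transcript_id"
    return df


@dataclass
class ContextScoreModel:
    """Position-specific relative-adaptiveness weights around the mAUG.

    ``weights[pos][base]`` for signed positions -6..-1 and +4..+6 (the AUG
    itself is excluded).  Weights lie in (0, 1] with the per-position
    maximum equal to 1, so a consensus sequence scores 1.  The score is the
    geometric mean of the weights at the nine scored positions.
    """

    weights: dict[int, dict[str, float]]
    positions: tuple[int, ...] = (-6, -5, -4, -3, -2, -1, 4, 5, 6)

    def __post_init__(self) -> None:
        for pos in self.positions:
            if pos not in self.weights:
                raise ValueError(f"missing weights for position {pos}")
            w = self.weights[pos]
            if any(not (0 < v <= 1) for v in w.values()):
                raise ValueError(f"weights at position {pos} must lie in (0, 1]")

    @classmethod
    def uniform(cls) -> "ContextScoreModel":
        return cls({p: {b: 1.0 for b in "ACGT"} for p in (-6, -5, -4, -3, -2, -1, 4, 5, 6)})

    @classmethod
    def synthetic_default(cls, seed: int = 20240205) -> "ContextScoreModel":
        """A fixed pseudo-random model for testing; A-rich consensus."""
        rng = np.random.default_rng(seed)
        weights = {}
        for p in (-6, -5, -4, -3, -2, -1, 4, 5, 6):
            raw = rng.uniform(0.15, 0.9, size=4)
            raw[0] = 1.0  # consensus base A at every position
            weights[p] = dict(zip("ACGT", raw))
        return cls(weights)

    def consensus(self) -> dict[int, str]:
        return {p: max(self.weights[p], key=self.weights[p].get) for p in self.positions}


def compute_context_score(
    sequence: str, annot: TranscriptAnnotation, model: ContextScoreModel
) -> float:
    """Geometric-mean context score of the mAUG, NaN when utr5_len < 6."""
    if annot.utr5_len < 6:
        return float("nan")
    logs = []
    for p in model.positions:
        coord = annot.cds_start + p - 1 if p > 0 else annot.cds_start + p
        if coord < 1 or coord > len(sequence):
            return float("nan")
        base = sequence[coord - 1].upper()
        w = model.weights[p].get(base)
        if w is None:
            return float("nan")
        logs.append(np.log(w))
    return float(np.exp(np.mean(logs)))


def bin_equal_size(values: pd.Series, k: int = 6) -> pd.Series:
    """Assign ranked values to k contiguous equal-size bins (1..k).

    Stable sort by (value, index) so ties break deterministically; the first
    ``n mod k`` bins take the extra element.  NaNs are dropped.
    """
    values = values.dropna()
    n = len(values)
    if n < k:
        raise ValueError(f"need at least k={k} finite values, got {n}")
    order = values.reset_index()
    order.columns = ["_id", "_val"]
    order = order.sort_values(["_val", "_id"], kind="mergesort")
    base, extra = divmod(n, k)
    sizes = [base + 1] * extra + [base] * (k - extra)
    labels = np.repeat(np.arange(1, k + 1), sizes)
    return pd.Series(labels, index=pd.Index(order["_id"], name=values.index.name), name="bin").reindex(values.index)


def summarize_bins(metric: pd.Series, assignments: pd.Series) -> pd.DataFrame:
    """Per-bin n, mean, median and quartiles of ``metric``.

    Transcripts lacking the metric or a bin assignment are dropped.
    """
    df = pd.DataFrame({"metric": metric, "bin": assignments}).dropna()
    rows = []
    for b, grp in df.groupby("bin"):
        v = grp["metric"]
        rows.append(
            {
                "bin": int(b),
                "n": len(v),
                "mean": v.mean(),
                "median": v.median(),
                "q1": v.quantile(0.25),
                "q3": v.quantile(0.75),
                "min": v.min(),
                "max": v.max(),
            }
        )
    return pd.DataFrame(rows).set_index("bin").sort_index()


def _sig_sets(results: pd.DataFrame) -> tuple[set, set]:
    up = set(results.index[results["class"] == "up"])
    down = set(results.index[results["class"] == "down"])
    return up, down


def classify_leaky_scanning(
    diff_mrpf: pd.DataFrame,
    diff_irpf: pd.DataFrame,
    mrpf_means: pd.DataFrame,
    irpf_means: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    magnitude_frac: float = 0.5,
) -> dict[str, set]:
    """Nested reciprocal mRPF-down / iRPF-up sets.

    set1: mRPF significantly down (class column of ``diff_mrpf``);
    set2: subset with iRPF significantly up;
    set3 ("leaky"): subset where the iRPF gain covers at least
    ``magnitude_frac`` of the mRPF loss in normalized read units, using
    condition-level replicate means from ``*_means`` (transcripts x
    conditions).
    """
    if set(diff_mrpf.index) != set(diff_irpf.index):
        raise ValueError("mRPF and iRPF contrasts cover different transcript universes")
    _, m_down = _sig_sets(diff_mrpf)
    i_up, _ = _sig_sets(diff_irpf)
    set1 = m_down
    set2 = set1 & i_up
    set3 = set()
    for tx in set2:
        m_loss = mrpf_means.at[tx, cond_a] - mrpf_means.at[tx, cond_b]
        i_gain = irpf_means.at[tx, cond_b] - irpf_means.at[tx, cond_a]
        if i_gain >= magnitude_frac * m_loss:
            set3.add(tx)
    return {"mrpf_down": set1, "reciprocal_sig": set2, "leaky": set3}


def classify_uaug_reciprocity(
    diff_urpf: pd.DataFrame,
    diff_mrpf: pd.DataFrame,
    urpf_means: pd.DataFrame,
    mrpf_means: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    magnitude_frac: float = 0.5,
) -> set:
    """Transcripts with uRPF significantly down, mRPF significantly up, and a
    uRPF loss of at least ``magnitude_frac`` of the mRPF gain."""
    if set(diff_urpf.index) != set(diff_mrpf.index):
        raise ValueError("uRPF and mRPF contrasts cover different transcript universes")
    _, u_down = _sig_sets(diff_urpf)
    m_up, _ = _sig_sets(diff_mrpf)
    out = set()
    for tx in u_down & m_up:
        u_loss = urpf_means.at[tx, cond_a] - urpf_means.at[tx, cond_b]
        m_gain = mrpf_means.at[tx, cond_b] - mrpf_means.at[tx, cond_a]
        if u_loss >= magnitude_frac * m_gain:
            out.add(tx)
    return out


def rro_by_context(
    rro: pd.DataFrame,
    context_scores: pd.Series,
    cond_a: str,
    cond_b: str,
    k: int = 6,
) -> pd.DataFrame:
    """Mean RRO per condition and mean log2 RRO ratio, binned by context score.

    ``rro`` is transcripts x conditions.  Transcripts without a finite
    context score or with RRO undefined in either condition are dropped.
    """
    df = pd.DataFrame({"ctx": context_scores, "a": rro[cond_a], "b": rro[cond_b]}).dropna()
    df = df[(df["a"] > 0)]
    bins = bin_equal_size(df["ctx"], k=k)
    df["bin"] = bins
    rows = []
    for b, grp in df.groupby("bin"):
        pos = grp[(grp["a"] > 0) & (grp["b"] > 0)]
        log2_delta = np.log2(pos["b"] / pos["a"]).mean() if len(pos) else float("nan")
        rows.append(
            {
                "bin": int(b),
                "n": len(grp),
                "context_mid": grp["ctx"].median(),
                f"mean_rro_{cond_a}": grp["a"].mean(),
                f"mean_rro_{cond_b}": grp["b"].mean(),
                "mean_log2_delta_rro": log2_delta,
                "delta_rro_of_means": grp["b"].mean() / grp["a"].mean(),
            }
        )
    return pd.DataFrame(rows).set_index("bin").sort_index()


def rank_heatmap_table(deltas: pd.DataFrame, ordering_contrast: str) -> pd.DataFrame:
    """Log2 delta matrix row-ordered by one contrast, most increased first.

    ``deltas`` is transcripts x contrasts (ratio scale); ties break by
    transcript id.
    """
    if ordering_contrast not in deltas.columns:
        raise KeyError(f"ordering contrast {ordering_contrast!r} not in table")
    log2 = np.log2(deltas)
    order = log2.reset_index()
    idx_col = order.columns[0]
    order = order.sort_values([ordering_contrast, idx_col], ascending=[False, True], kind="mergesort")
    return log2.loc[order[idx_col]]
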