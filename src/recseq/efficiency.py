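"""Recruitment efficiency (RE), relative ribosome occupancy (RRO) and
between-condition deltas.

RE = spike-normalized mRPF / mRNA density, where mRNA density is RNA-seq
reads with 5' ends inside the CDS divided by CDS length (reads per nt).
RRO = iRPF / cdsRPF, the fraction of CDS-mapped complexes sitting at
internal positions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotations import Annotations

__all__ = [
    "compute_mrna_density",
    "compute_re",
    "compute_rro",
    "condition_means",
    "delta_between_conditions",
    "urpf_mrpf_ratio",
]


def compute_mrna_density(rnaseq: pd.DataFrame, annots: Annotations) -> pd.Series:
    """Reads-per-nt of the CDS for every annotated transcript.

    ``rnaseq`` has columns ``transcript_id, position, count`` with 1-based
    5'-end positions.  Reads outside the CDS do not contribute.  Transcripts
    with no reads get density 0.
    """
    density = pd.Series(0.0, index=pd.Index(annots.ids(), name="transcript_id"))
    if len(rnaseq):
        unknown = set(rnaseq["transcript_id"].unique()) - set(annots.ids())
        if unknown:
            raise KeyError(f"RNA-seq reads on unknown transcripts: {sorted(unknown)}")
        for tx, grp in rnaseq.groupby("transcript_id"):
            a = annots[tx]
            inside = grp["position"].between(a.cds_start, a.cds_end)
            density[tx] = grp.loc[inside, "count"].sum() / a.cds_len
    return density


def compute_re(norm_mrpf: pd.Series, density: pd.Series) -> pd.Series:
    """RE = normalized mRPF / density; NaN (excluded) where density == 0."""
    density = density.reindex(norm_mrpf.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        re = norm_mrpf / density
    re[density <= 0] = np.nan
    return re


def compute_rro(irpf: pd.Series, cdsrpf: pd.Series) -> pd.Series:
    """RRO = iRPF / cdsRPF; NaN where cdsRPF == 0.  iRPF > cdsRPF is an error."""
    cdsrpf = cdsrpf.reindex(irpf.index)
    bad = irpf > cdsrpf
    if bad.any():
        raise ValueError(f"iRPF exceeds cdsRPF for {list(irpf.index[bad])[:5]}")
    with np.errstate(divide="ignore", invalid="ignore"):
        rro = irpf / cdsrpf
    rro[cdsrpf <= 0] = np.nan
    return rro


def condition_means(
    table: pd.DataFrame, conditions: pd.Series, column: str
) -> pd.DataFrame:
    """Replicate-mean of one column per (condition, transcript).

    ``table`` is indexed by (sample_id, transcript_id); returns transcripts x
    conditions.
    """
    df = table[column].reset_index()
    df["condition"] = df["sample_id"].map(conditions)
    if df["condition"].isna().any():
        missing = df.loc[df["condition"].isna(), "sample_id"].unique()
        raise KeyError(f"samples without condition assignment: {list(missing)}")
    return df.pivot_table(index="transcript_id", columns="condition", values=column, aggfunc="mean")


def delta_between_conditions(
    metric: pd.DataFrame, cond_a: str, cond_b: str
) -> pd.Series:
    """Per-transcript ratio metric(B)/metric(A); NaN where either is undefined
    or the denominator is zero (excluded, never infinite)."""
    for c in (cond_a, cond_b):
        if c not in metric.columns:
            raise KeyError(f"condition {c!r} missing from metric table")
    a = metric[cond_a]
    b = metric[cond_b]
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = b / a
    delta[(a <= 0) | ~np.isfinite(a) | ~np.isfinite(b)] = np.nan
    delta.name = f"delta_{cond_b}_over_{cond_a}"
    return delta


def urpf_mrpf_ratio(
    counts: pd.DataFrame,
    exclude: set[str] | None = None,
    urpf_col: str = "uRPF_norm",
    mrpf_col: str = "mRPF_norm",
) -> tuple[float, pd.Series]:
    """Translatome-wide sum(uRPF)/sum(mRPF) with an exclusion list.

    ``counts`` is indexed by transcript (or (sample, transcript); sums run
    over all rows).  Returns the ratio plus each excluded transcript's share
    of the grand uRPF total (before exclusion).
    """
    exclude = set(exclude or ())
    tx = counts.index.get_level_values("transcript_id") if isinstance(counts.index, pd.MultiIndex) else counts.index
    total_u_all = counts[urpf_col].sum()
    mask = ~pd.Index(tx).isin(exclude)
    total_u = counts.loc[mask, urpf_col].sum()
    total_m = counts.loc[mask, mrpf_col].sum()
    if total_m <= 0:
        raise ValueError("total mRPF is zero after exclusions")
    shares = {}
    for t in sorted(exclude):
        sel = pd.Index(tx) == t
        shares[t] = counts.loc[sel, urpf_col].sum() / total_u_all if total_u_all > 0 else 0.0
    return float(total_u / total_m), pd.Series(shares, dtype=float, name="urpf_share")
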