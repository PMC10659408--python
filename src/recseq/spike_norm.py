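"""Spike-in based size factors.

Each sample receives a fixed amount of pre-formed 48S complexes on
non-native spike transcripts.  Reads whose P-site falls in the [-3, +6]
window around each designated spike AUG (main or internal) define one
counting category; per-sample geometric means over categories, rescaled so
the largest sample equals 1, give the size factors.  Normalized count =
raw / size_factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import Annotations
from .psite_counting import PsiteConfig, _psite_positions

__all__ = ["SpikeInReference", "SizeFactorSet", "count_spike_categories", "compute_spike_size_factors", "apply_size_factors"]


@dataclass
class SpikeInReference:
    """Counting categories on spike transcripts.

    ``categories`` maps category label -> (spike transcript id, 1-based AUG
    position).  The window is signed relative to each category's AUG with
    A = +1 (no position 0), same convention as mRPF counting.
    """

    categories: dict[str, tuple[str, int]]
    window: tuple[int, int] = (-3, 6)

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise ValueError("spike-in reference needs at least 2 categories")
        spans: dict[str, list[tuple[int, int]]] = {}
        for label, (tx, aug) in self.categories.items():
            lo = aug + self.window[0]
            hi = aug + self.window[1] - 1  # +6 signed == aug + 5 in coords
            for a, b in spans.setdefault(tx, []):
                if lo <= b and a <= hi:
                    raise ValueError(f"overlapping spike windows on {tx} (category {label})")
            spans[tx].append((lo, hi))

    def spike_transcripts(self) -> set[str]:
        return {tx for tx, _ in self.categories.values()}

    def to_frame(self) -> pd.DataFrame:
        rows = [(label, tx, aug) for label, (tx, aug) in self.categories.items()]
        return pd.DataFrame(rows, columns=["category", "transcript_id", "aug_pos"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SpikeInReference":
        df = pd.read_csv(path, sep="\t")
        return cls({r.category: (r.transcript_id, int(r.aug_pos)) for r in df.itertuples()})


@dataclass
class SizeFactorSet:
    """Per-sample spike geometric means and derived size factors."""

    factors: pd.Series  # sample -> factor in (0, 1]
    geometric_means: pd.Series
    reference_sample: str
    category_counts: pd.DataFrame = field(default=None)  # samples x categories

    def __getitem__(self, sample: str) -> float:
        return float(self.factors[sample])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"geometric_mean": self.geometric_means, "size_factor": self.factors})
        df.index.name = "sample_id"
        df["is_reference"] = df.index == self.reference_sample
        if self.category_counts is not None:
            df = pd.concat([self.category_counts, df], axis=1)
        return df


def count_spike_categories(
    footprints: pd.DataFrame,
    ref: SpikeInReference,
    annots: Annotations | None = None,
    cfg: PsiteConfig | None = None,
) -> pd.DataFrame:
    """Per-sample spike category counts (samples x categories).

    A sample with zero spike reads overall is a failed spike-in and raises.
    """
    cfg = cfg or PsiteConfig()
    spike_tx = ref.spike_transcripts()
    samples = sorted(footprints["sample_id"].unique())
    if not samples:
        raise ValueError("no footprints provided")
    df = footprints[
        footprints["transcript_id"].isin(spike_tx)
        & footprints["length"].between(cfg.min_len, cfg.max_len)
    ].copy()
    missing = set(samples) - set(df["sample_id"].unique())
    if missing:
        raise ValueError(f"samples with zero spike-in reads: {sorted(missing)}")

    psite = _psite_positions(df, cfg)
    out = pd.DataFrame(0, index=pd.Index(samples, name="sample_id"), columns=list(ref.categories))
    lo, hi = ref.window
    for label, (tx, aug) in ref.categories.items():
        rel = np.where(psite >= aug, psite - aug + 1, psite - aug)
        mask = (df["transcript_id"].to_numpy() == tx) & (rel >= lo) & (rel <= hi)
        if mask.any():
            tallied = df.loc[mask].groupby("sample_id")["count"].sum()
            out[label] = tallied.reindex(out.index, fill_value=0)
    return out.astype(int)


def compute_spike_size_factors(category_counts: pd.DataFrame, policy: str = "strict") -> SizeFactorSet:
    """Geometric-mean size factors, normalized to the max-geometric-mean sample.

    ``policy`` controls zero categories: "strict" raises naming the first
    offending (sample, category); "drop-zeros" removes any category that is
    zero in any sample symmetrically across all samples.
    """
    counts = category_counts.astype(float)
    zero_mask = counts <= 0
    if zero_mask.to_numpy().any():
        if policy == "strict":
            sample = zero_mask.any(axis=1).idxmax()
            category = zero_mask.loc[sample].idxmax()
            raise ValueError(f"zero spike-in count for sample {sample!r}, category {category!r}")
        elif policy == "drop-zeros":
            counts = counts.loc[:, ~zero_mask.any(axis=0)]
            if counts.shape[1] < 2:
                raise ValueError("fewer than 2 spike categories remain after dropping zeros")
        else:
            raise ValueError(f"unknown zero-handling policy {policy!r}")
    gm = pd.Series(np.exp(np.log(counts).mean(axis=1)), index=counts.index, name="geometric_mean")
    reference = gm.idxmax()
    factors = gm / gm[reference]
    factors.name = "size_factor"
    return SizeFactorSet(
        factors=factors,
        geometric_means=gm,
        reference_sample=str(reference),
        category_counts=category_counts,
    )


def apply_size_factors(region_counts: pd.DataFrame, sf: SizeFactorSet) -> pd.DataFrame:
    """Append ``<region>_norm`` columns (raw / sample size factor).

    ``region_counts`` is indexed by (sample_id, transcript_id); raw columns
    are left untouched.
    """
    samples = region_counts.index.get_level_values("sample_id").unique()
    missing = set(samples) - set(sf.factors.index)
    if missing:
        raise KeyError(f"no size factor for samples: {sorted(missing)}")
    out = region_counts.copy()
    per_row = sf.factors.reindex(region_counts.index.get_level_values("sample_id")).to_numpy()
    for col in list(region_counts.columns):
        out[f"{col}_norm"] = region_counts[col].to_numpy() / per_row
    return out
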