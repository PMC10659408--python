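"""P-site assignment, region counting, metagene matrices and coverage tracks.

Footprints are tables with columns ``sample_id, transcript_id,
five_prime_pos, length, count`` (1-based transcript coordinates, count =
multiplicity).  The P-site codon position of a footprint is its 5' end plus
a fixed, length-configurable offset (default +12 nt).

Region windows (closed intervals in signed mAUG-relative coordinates, with
A-of-AUG = +1 and no position 0):

====== ==========================================
mRPF   [-3, +6]
iRPF   [+9, last nt of the stop codon]
cdsRPF [-3, last nt of the stop codon]
uRPF   [transcript 5' end, -5]
====== ==========================================

Positions -4 and +7/+8 deliberately belong to no u/m/i category; cdsRPF is
a superset of mRPF and iRPF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotations import Annotations, to_signed

__all__ = [
    "PsiteConfig",
    "FOOTPRINT_COLUMNS",
    "REGION_COLUMNS",
    "make_footprint_frame",
    "assign_psite",
    "count_regions",
    "build_metagene",
    "export_tracks",
    "write_wiggle",
    "read_wiggle",
]

FOOTPRINT_COLUMNS = ["sample_id", "transcript_id", "five_prime_pos", "length", "count"]
REGION_COLUMNS = ["mRPF", "uRPF", "iRPF", "cdsRPF"]


@dataclass
class PsiteConfig:
    """P-site offsets, read-length filter and region windows."""

    min_len: int = 25
    max_len: int = 34
    default_offset: int = 12
    offset_by_length: dict[int, int] = field(default_factory=dict)
    # signed mAUG-relative closed windows; stop end substitutes None bounds
    mrpf_window: tuple[int, int] = (-3, 6)
    irpf_start: int = 9
    cds_window_start: int = -3
    urpf_end: int = -5

    def offset(self, length: int) -> int:
        return self.offset_by_length.get(length, self.default_offset)

    def __post_init__(self) -> None:
        offsets = set(self.offset_by_length.values()) | {self.default_offset}
        for off in offsets:
            if not (0 < off < self.min_len):
                raise ValueError(f"P-site offset {off} must be in (0, min_len)")


def make_footprint_frame(rows: list[tuple] | None = None) -> pd.DataFrame:
    """Build an empty or populated footprint table with canonical columns."""
    df = pd.DataFrame(rows or [], columns=FOOTPRINT_COLUMNS)
    return df.astype(
        {"sample_id": str, "transcript_id": str, "five_prime_pos": int, "length": int, "count": int}
    )


def assign_psite(
    five_prime_pos: int, length: int, cds_start: int, cfg: PsiteConfig | None = None
) -> int:
    """Signed P-site position of one footprint relative to the main AUG.

    Raises ``ValueError`` for lengths outside the configured filter; callers
    doing bulk counting should filter instead (see :func:`count_regions`).
    """
    cfg = cfg or PsiteConfig()
    if not (cfg.min_len <= length <= cfg.max_len):
        raise ValueError(f"footprint length {length} outside [{cfg.min_len}, {cfg.max_len}]")
    return to_signed(five_prime_pos + cfg.offset(length), cds_start)


def _psite_positions(df: pd.DataFrame, cfg: PsiteConfig) -> np.ndarray:
    """Vectorized 1-based transcript coordinate of the P-site for each row."""
    lengths = df["length"].to_numpy()
    offsets = np.full(len(df), cfg.default_offset, dtype=int)
    for ln, off in cfg.offset_by_length.items():
        offsets[lengths == ln] = off
    return df["five_prime_pos"].to_numpy() + offsets


def _annot_lookup(annots: Annotations) -> pd.DataFrame:
    rows = [(a.transcript_id, a.cds_start, a.cds_end, a.tx_len) for a in annots]
    return pd.DataFrame(rows, columns=["transcript_id", "cds_start", "cds_end", "tx_len"]).set_index(
        "transcript_id"
    )


def count_regions(
    footprints: pd.DataFrame,
    annots: Annotations,
    cfg: PsiteConfig | None = None,
    discard_log: dict | None = None,
) -> pd.DataFrame:
    """Count mRPF/uRPF/iRPF/cdsRPF per (sample, transcript).

    Returns a table indexed by (sample_id, transcript_id) covering every
    transcript in ``annots`` crossed with every sample present in
    ``footprints``; transcripts without reads get zero rows.  Footprints on
    unknown transcripts raise; out-of-length-range footprints are dropped
    and tallied in ``discard_log`` if given.
    """
    cfg = cfg or PsiteConfig()
    samples = sorted(footprints["sample_id"].unique()) if len(footprints) else []
    tx_ids = annots.ids()
    index = pd.MultiIndex.from_product([samples, tx_ids], names=["sample_id", "transcript_id"])
    out = pd.DataFrame(0, index=index, columns=REGION_COLUMNS, dtype=int)
    if not len(footprints):
        return out

    unknown = set(footprints["transcript_id"].unique()) - set(tx_ids)
    if unknown:
        raise KeyError(f"footprints reference unknown transcripts: {sorted(unknown)}")

    keep = footprints["length"].between(cfg.min_len, cfg.max_len)
    if discard_log is not None:
        discard_log["length_filtered"] = int(footprints.loc[~keep, "count"].sum())
    df = footprints.loc[keep].copy()
    if not len(df):
        return out

    lut = _annot_lookup(annots)
    cds_start = lut["cds_start"].reindex(df["transcript_id"]).to_numpy()
    cds_end = lut["cds_end"].reindex(df["transcript_id"]).to_numpy()
    psite = _psite_positions(df, cfg)
    # signed positions relative to the mAUG, skipping 0
    rel = np.where(psite >= cds_start, psite - cds_start + 1, psite - cds_start)
    stop_rel = cds_end - cds_start + 1

    counts = df["count"].to_numpy()
    lo, hi = cfg.mrpf_window
    masks = {
        "mRPF": (rel >= lo) & (rel <= hi),
        "uRPF": (psite >= 1) & (rel <= cfg.urpf_end),
        "iRPF": (rel >= cfg.irpf_start) & (rel <= stop_rel),
        "cdsRPF": (rel >= cfg.cds_window_start) & (rel <= stop_rel),
    }
    key = pd.MultiIndex.from_frame(df[["sample_id", "transcript_id"]])
    for region, mask in masks.items():
        if mask.any():
            tallied = pd.Series(counts[mask], index=key[mask]).groupby(level=[0, 1]).sum()
            out[region] = out[region].add(tallied.reindex(out.index, fill_value=0), fill_value=0)
    return out.astype(int)


def build_metagene(
    footprints: pd.DataFrame,
    annots: Annotations,
    window: tuple[int, int] = (-50, 100),
    cfg: PsiteConfig | None = None,
) -> pd.DataFrame:
    """Metagene matrix: rows = footprint lengths, columns = signed 5'-end
    positions relative to the mAUG over ``window`` (position 0 omitted).

    Cell (L, p) is the summed count of length-L footprints whose 5' end maps
    to relative position p on any transcript.
    """
    cfg = cfg or PsiteConfig()
    lo, hi = window
    if lo >= hi:
        raise ValueError("window bounds must satisfy lo < hi")
    cols = [p for p in range(lo, hi + 1) if p != 0]
    lengths = list(range(cfg.min_len, cfg.max_len + 1))
    mat = pd.DataFrame(0.0, index=pd.Index(lengths, name="length"), columns=pd.Index(cols, name="rel_pos"))
    if not len(footprints):
        return mat

    keep = footprints["length"].between(cfg.min_len, cfg.max_len)
    df = footprints.loc[keep]
    if not len(df):
        return mat
    lut = _annot_lookup(annots)
    cds_start = lut["cds_start"].reindex(df["transcript_id"]).to_numpy()
    fp = df["five_prime_pos"].to_numpy()
    rel = np.where(fp >= cds_start, fp - cds_start + 1, fp - cds_start)
    inside = (rel >= lo) & (rel <= hi)
    tallied = (
        pd.DataFrame(
            {"length": df["length"].to_numpy()[inside], "rel_pos": rel[inside], "count": df["count"].to_numpy()[inside]}
        )
        .groupby(["length", "rel_pos"])["count"]
        .sum()
    )
    for (ln, p), v in tallied.items():
        mat.at[ln, p] += v
    return mat


# ---------------------------------------------------------------------------
# wiggle tracks (transcript-space, variableStep, 1-based)


def write_wiggle(tracks: Mapping[str, Mapping[int, float]], path: str | Path, precision: int = 6) -> None:
    with open(path, "w") as fh:
        for chrom in tracks:
            fh.write(f"variableStep chrom={chrom}\n")
            for pos in sorted(tracks[chrom]):
                fh.write(f"{pos}\t{tracks[chrom][pos]:.{precision}f}\n")


def read_wiggle(path: str | Path) -> dict[str, dict[int, float]]:
    tracks: dict[str, dict[int, float]] = {}
    current: dict[int, float] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("variableStep"):
                chrom = dict(kv.split("=") for kv in line.split()[1:])["chrom"]
                current = tracks.setdefault(chrom, {})
            else:
                if current is None:
                    raise ValueError("wiggle data before any variableStep header")
                pos, val = line.split("\t")
                current[int(pos)] = float(val)
    return tracks


def export_tracks(
    footprints: pd.DataFrame,
    annots: Annotations,
    path: str | Path,
    size_factors: Mapping[str, float] | None = None,
    samples: list[str] | None = None,
    use_psite: bool = True,
    average: bool = False,
    cfg: PsiteConfig | None = None,
) -> None:
    """Write per-sample (or replicate-averaged) wiggle tracks.

    One file per sample named ``<path stem>.<sample>.wig``, or a single
    averaged track at ``path`` when ``average`` is set.  Values are counts
    divided by the sample's size factor (1.0 if absent).
    """
    cfg = cfg or PsiteConfig()
    path = Path(path)
    size_factors = dict(size_factors or {})
    if samples is None:
        samples = sorted(footprints["sample_id"].unique())

    per_sample: dict[str, dict[str, dict[int, float]]] = {}
    for sample in samples:
        df = footprints[
            (footprints["sample_id"] == sample)
            & footprints["length"].between(cfg.min_len, cfg.max_len)
        ]
        sf = size_factors.get(sample, 1.0)
        pos = _psite_positions(df, cfg) if use_psite else df["five_prime_pos"].to_numpy()
        tall = (
            pd.DataFrame({"transcript_id": df["transcript_id"].to_numpy(), "pos": pos, "count": df["count"].to_numpy()})
            .groupby(["transcript_id", "pos"])["count"]
            .sum()
        )
        tracks: dict[str, dict[int, float]] = {}
        for (tx, p), v in tall.items():
            tracks.setdefault(tx, {})[int(p)] = v / sf
        per_sample[sample] = tracks

    if average:
        merged: dict[str, dict[int, float]] = {}
        for tracks in per_sample.values():
            for tx, d in tracks.items():
                tgt = merged.setdefault(tx, {})
                for p, v in d.items():
                    tgt[p] = tgt.get(p, 0.0) + v / len(per_sample)
        write_wiggle(merged, path)
    else:
        for sample, tracks in per_sample.items():
            write_wiggle(tracks, path.with_suffix(f".{sample}.wig"))
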