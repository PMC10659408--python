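"""Transcript geometry and annotation tables.

All coordinates are 1-based transcript coordinates (5'->3').  Signed
positions relative to the main AUG use the convention A-of-AUG = +1, the
nucleotide immediately 5' of it = -1, and position 0 does not exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import math

import pandas as pd

__all__ = [
    "TranscriptAnnotation",
    "Annotations",
    "to_signed",
    "from_signed",
    "read_fasta",
    "write_fasta",
]


def to_signed(pos: int, cds_start: int) -> int:
    """Map a 1-based transcript coordinate to a signed mAUG-relative position.

    ``pos == cds_start`` maps to +1, ``pos == cds_start - 1`` maps to -1;
    there is no position 0.
    """
    return pos - cds_start + 1 if pos >= cds_start else pos - cds_start


def from_signed(rel: int, cds_start: int) -> int:
    """Inverse of :func:`to_signed`."""
    if rel == 0:
        raise ValueError("signed position 0 does not exist under this convention")
    return cds_start + rel - 1 if rel > 0 else cds_start + rel


@dataclass
class TranscriptAnnotation:
    """Geometry and per-transcript covariates for one transcript."""

    transcript_id: str
    utr5_len: int
    cds_start: int
    cds_end: int
    tx_len: int
    internal_aug_positions: list[int] = field(default_factory=list)
    upstream_start_positions: list[int] = field(default_factory=list)
    context_score: float = float("nan")
    is_spikein: bool = False
    excluded_from_uorf_totals: bool = False

    def __post_init__(self) -> None:
        if self.utr5_len != self.cds_start - 1:
            raise ValueError(
                f"{self.transcript_id}: utr5_len ({self.utr5_len}) must equal "
                f"cds_start - 1 ({self.cds_start - 1})"
            )
        if self.cds_end <= self.cds_start:
            raise ValueError(f"{self.transcript_id}: cds_end must exceed cds_start")
        if self.tx_len < self.cds_end:
            raise ValueError(f"{self.transcript_id}: tx_len shorter than cds_end")

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start + 1


class Annotations:
    """An ordered collection of :class:`TranscriptAnnotation` keyed by id."""

    def __init__(self, records: Iterable[TranscriptAnnotation] = ()):
        self._records: dict[str, TranscriptAnnotation] = {}
        for rec in records:
            if rec.transcript_id in self._records:
                raise ValueError(f"duplicate transcript id {rec.transcript_id!r}")
            self._records[rec.transcript_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[TranscriptAnnotation]:
        return iter(self._records.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._records

    def __getitem__(self, transcript_id: str) -> TranscriptAnnotation:
        return self._records[transcript_id]

    def ids(self) -> list[str]:
        return list(self._records)

    def add(self, rec: TranscriptAnnotation) -> None:
        if rec.transcript_id in self._records:
            raise ValueError(f"duplicate transcript id {rec.transcript_id!r}")
        self._records[rec.transcript_id] = rec

    def subset(self, ids: Iterable[str]) -> "Annotations":
        return Annotations(self._records[i] for i in ids)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self:
            rows.append(
                {
                    "transcript_id": r.transcript_id,
                    "utr5_len": r.utr5_len,
                    "cds_start": r.cds_start,
                    "cds_end": r.cds_end,
                    "tx_len": r.tx_len,
                    "internal_aug_positions": ",".join(map(str, r.internal_aug_positions)),
                    "upstream_start_positions": ",".join(map(str, r.upstream_start_positions)),
                    "context_score": r.context_score,
                    "is_spikein": int(r.is_spikein),
                    "excluded_from_uorf_totals": int(r.excluded_from_uorf_totals),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "transcript_id",
                "utr5_len",
                "cds_start",
                "cds_end",
                "tx_len",
                "internal_aug_positions",
                "upstream_start_positions",
                "context_score",
                "is_spikein",
                "excluded_from_uorf_totals",
            ],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Annotations":
        def _parse_list(v: object) -> list[int]:
            if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
                return []
            # pandas may read a single-entry list column as a float
            return [int(float(x)) for x in str(v).split(",") if x != ""]

        records = []
        for row in df.itertuples(index=False):
            records.append(
                TranscriptAnnotation(
                    transcript_id=str(row.transcript_id),
                    utr5_len=int(row.utr5_len),
                    cds_start=int(row.cds_start),
                    cds_end=int(row.cds_end),
                    tx_len=int(row.tx_len),
                    internal_aug_positions=_parse_list(getattr(row, "internal_aug_positions", "")),
                    upstream_start_positions=_parse_list(getattr(row, "upstream_start_positions", "")),
                    context_score=float(getattr(row, "context_score", float("nan"))),
                    is_spikein=bool(int(getattr(row, "is_spikein", 0))),
                    excluded_from_uorf_totals=bool(int(getattr(row, "excluded_from_uorf_totals", 0))),
                )
            )
        return cls(records)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Annotations":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader returning an ordered id -> sequence mapping."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
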