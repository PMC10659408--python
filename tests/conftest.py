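import numpy as np
import pandas as pd
import pytest

from recseq.annotations import Annotations, TranscriptAnnotation
from recseq.psite_counting import make_footprint_frame
from recseq.synthetic_data import SyntheticConfig, simulate_dataset


@pytest.fixture
def tiny_annots():
    """Two hand-built transcripts with known geometry."""
    return Annotations(
        [
            TranscriptAnnotation(
                transcript_id="T1",
                utr5_len=40,
                cds_start=41,
                cds_end=140,  # 100 nt CDS
                tx_len=170,
                internal_aug_positions=[60, 90],
                upstream_start_positions=[10],
            ),
            TranscriptAnnotation(
                transcript_id="T2",
                utr5_len=20,
                cds_start=21,
                cds_end=80,
                tx_len=100,
                internal_aug_positions=[35],
                upstream_start_positions=[],
            ),
        ]
    )


@pytest.fixture
def fp_factory():
    def make(rows):
        return make_footprint_frame(rows)

    return make


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SyntheticConfig(
        n_transcripts=40,
        pic_pool=60_000,
        seed=5,
        utr5_len_log_mean=3.8,
        utr5_len_log_sd=0.4,
        rnaseq_reads_per_nt=0.3,
    )
    return simulate_dataset(cfg)


def brute_force_region_counts(footprints, annots, offset=12, min_len=25, max_len=34):
    """Independent per-read interval-membership oracle."""
    out = {}
    samples = sorted(set(footprints["sample_id"]))
    for s in samples:
        for a in annots:
            out[(s, a.transcript_id)] = {"mRPF": 0, "uRPF": 0, "iRPF": 0, "cdsRPF": 0}
    for row in footprints.itertuples(index=False):
        if not (min_len <= row.length <= max_len):
            continue
        a = annots[row.transcript_id]
        psite = row.five_prime_pos + offset
        rel = psite - a.cds_start + 1 if psite >= a.cds_start else psite - a.cds_start
        stop_rel = a.cds_end - a.cds_start + 1
        key = (row.sample_id, row.transcript_id)
        if -3 <= rel <= 6:
            out[key]["mRPF"] += row.count
        if psite >= 1 and rel <= -5:
            out[key]["uRPF"] += row.count
        if 9 <= rel <= stop_rel:
            out[key]["iRPF"] += row.count
        if -3 <= rel <= stop_rel:
            out[key]["cdsRPF"] += row.count
    df = pd.DataFrame.from_dict(out, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["sample_id", "transcript_id"])
    return df.sort_index()


def random_instance(rng, n_tx=5, n_reads=50):
    """Random small counting instance (annotations + in-bounds footprints)."""
    annots = Annotations()
    for i in range(rng.integers(1, n_tx + 1)):
        utr5 = int(rng.integers(0, 60))
        cds_len = int(rng.integers(2, 40)) * 3
        tx_len = utr5 + cds_len + int(rng.integers(0, 40))
        annots.add(
            TranscriptAnnotation(
                transcript_id=f"R{i}",
                utr5_len=utr5,
                cds_start=utr5 + 1,
                cds_end=utr5 + cds_len,
                tx_len=tx_len,
            )
        )
    ids = annots.ids()
    rows = []
    for _ in range(int(rng.integers(0, n_reads + 1))):
        tx = ids[rng.integers(0, len(ids))]
        a = annots[tx]
        length = int(rng.integers(24, 36))  # includes out-of-range lengths
        if a.tx_len <= length:
            continue
        pos = int(rng.integers(1, a.tx_len - length + 2))
        rows.append((f"s{rng.integers(0, 2)}", tx, pos, length, int(rng.integers(1, 4))))
    return annots, make_footprint_frame(rows)
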