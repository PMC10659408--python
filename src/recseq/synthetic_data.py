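"""Synthetic transcriptome and 48S footprint generator.

Emulates the generative process the downstream analysis assumes: a limiting
pool of scanning complexes allocated across transcripts by recruitment
weight, helicase-concentration-dependent relief of 5'UTR structure/length
penalties with saturation, context-dependent readthrough of the main start
codon to internal AUGs, rare upstream-start initiation, constant spike-in
complexes scaled by per-sample loss factors, footprints of 25-34 nt with 5'
ends ~12 nt upstream of the P-site codon, and NB count noise.

Every stochastic stage draws from an RNG stream keyed by (master seed,
stage, sample) so stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotations import Annotations, TranscriptAnnotation, write_fasta
from .feature_analysis import ContextScoreModel, compute_context_score, compute_pars_summaries
from .psite_counting import FOOTPRINT_COLUMNS, make_footprint_frame
from .spike_norm import SpikeInReference

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "default_spike_reference",
    "generate_transcriptome",
    "compute_recruitment_weights",
    "simulate_footprints",
    "simulate_spikeins",
    "simulate_rnaseq",
    "simulate_dataset",
    "write_dataset",
]

# stage codes for per-(seed, stage, sample) RNG streams
_STAGE_TRANSCRIPTOME = 0
_STAGE_FOOTPRINTS = 1
_STAGE_SPIKES = 2
_STAGE_RNASEQ = 3
_STAGE_LOSSES = 4

_DEFAULT_LEN_PROBS = {
    25: 0.02, 26: 0.04, 27: 0.08, 28: 0.16, 29: 0.25,
    30: 0.20, 31: 0.12, 32: 0.07, 33: 0.04, 34: 0.02,
}


@dataclass
class SyntheticConfig:
    """All knobs of the generative model; defaults give a small, well-behaved
    dataset with mild planted effects."""

    n_transcripts: int = 50
    # 5'UTR lengths ~ round(lognormal); a fixed value overrides the draw
    utr5_len_log_mean: float = 3.6
    utr5_len_log_sd: float = 0.6
    utr5_len_fixed: int | None = None
    # CDS lengths ~ lognormal rounded to a multiple of 3, floored at min
    cds_len_log_mean: float = 6.2
    cds_len_log_sd: float = 0.35
    cds_len_min: int = 60
    utr3_len: int = 30
    # per-nt structure scores: per-transcript level + per-nt noise
    pars_level_mean: float = 0.0
    pars_level_sd: float = 1.0
    pars_nt_sd: float = 0.5
    # transcript abundances ~ lognormal, mean-normalized
    abundance_log_sd: float = 0.6
    # recruitment model
    pic_pool: int = 100_000
    ded1_concs: tuple[float, ...] = (0.0, 500.0)
    ded1_K: float = 100.0
    penalty_alpha: float = 0.05   # per structure-score unit (Max30)
    penalty_beta: float = 0.01    # per nt of 5'UTR
    stim_mode: str = "penalty"    # penalty | uniform | flagged
    stim_scale: float = 0.25      # S = stim_scale * penalty  (penalty mode)
    stim_base: float = 0.0        # S = stim_base              (uniform mode)
    stim_frac: float = 0.1        # flagged mode: fraction of transcripts ...
    stim_S: float = 4.0           # ... given S = stim_S (others 0)
    stim_call_threshold: float = 2.0  # truth flag: stim_factor at top conc >= this
    # leaky scanning / upstream initiation
    leak_mode: str = "context"    # context | flagged
    leak_base: float = 0.02
    leak_context_slope: float = 0.0
    leak_ded1_mult: tuple[float, ...] = (1.0, 1.0)  # one per condition
    leak_high: float = 0.6        # flagged mode: planted leak prob in later conditions
    leak_planted_frac: float = 0.0
    leak_stop_prob: float = 0.5   # geometric stop rule while scanning AUGs
    uaug_init_prob: float = 0.0
    # spike-ins
    spike_counts: dict[str, float] = field(default_factory=dict)  # category -> expected RPFs
    # per-sample losses; None -> drawn log-uniform in [0.25, 1]
    sample_loss: dict[str, float] | None = None
    n_replicates: int = 3
    # count noise: "nb" (gamma-Poisson), "poisson", or "none" (deterministic)
    count_noise: str = "nb"
    nb_dispersion: float = 0.05
    # footprint geometry
    footprint_len_probs: dict[int, float] = field(default_factory=lambda: dict(_DEFAULT_LEN_PROBS))
    offset_jitter_probs: dict[int, float] = field(default_factory=lambda: {-12: 1.0})
    # RNA-seq: expected reads per nt per unit abundance
    rnaseq_reads_per_nt: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 0:
            raise ValueError("n_transcripts must be >= 0")
        if self.pic_pool < 0:
            raise ValueError("pic_pool must be >= 0")
        for name in ("leak_base", "leak_high", "uaug_init_prob", "stim_frac", "leak_planted_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0.0 < self.leak_stop_prob <= 1.0):
            raise ValueError("leak_stop_prob must lie in (0, 1]")
        if len(self.leak_ded1_mult) != len(self.ded1_concs):
            raise ValueError("leak_ded1_mult must have one entry per condition")
        for probs in (self.footprint_len_probs, self.offset_jitter_probs):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"probability vector sums to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError("probabilities must be non-negative")
        if any(not (25 <= ln <= 34) for ln in self.footprint_len_probs):
            raise ValueError("footprint lengths must lie in [25, 34]")
        if self.stim_mode not in ("penalty", "uniform", "flagged"):
            raise ValueError(f"unknown stim_mode {self.stim_mode!r}")
        if self.leak_mode not in ("context", "flagged"):
            raise ValueError(f"unknown leak_mode {self.leak_mode!r}")
        if self.count_noise not in ("nb", "poisson", "none"):
            raise ValueError(f"unknown count_noise {self.count_noise!r}")
        if not self.spike_counts:
            self.spike_counts = _default_spike_counts()

    @property
    def condition_names(self) -> list[str]:
        return [f"ded1_{c:g}" for c in self.ded1_concs]

    def sample_names(self) -> list[str]:
        return [f"{cond}_r{i + 1}" for cond in self.condition_names for i in range(self.n_replicates)]

    def sample_conditions(self) -> pd.Series:
        mapping = {
            f"{cond}_r{i + 1}": cond
            for cond in self.condition_names
            for i in range(self.n_replicates)
        }
        return pd.Series(mapping, name="condition")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["ded1_concs"] = list(self.ded1_concs)
        d["leak_ded1_mult"] = list(self.leak_ded1_mult)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("ded1_concs", "leak_ded1_mult"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        for key in ("footprint_len_probs", "offset_jitter_probs"):
            if key in d and d[key] is not None:
                d[key] = {int(k): float(v) for k, v in d[key].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# spike-in reference


def _spike_cds(n_iaugs: int, spacing_codons: int = 11) -> str:
    """CDS starting with ATG, with internal ATGs every ``spacing_codons``."""
    filler = "CCT"
    codons = ["ATG"]
    for _ in range(n_iaugs):
        codons.extend([filler] * (spacing_codons - 1))
        codons.append("ATG")
    codons.extend([filler] * 5)
    codons.append("TAA")
    return "".join(codons)


def _default_spike_counts() -> dict[str, float]:
    counts = {}
    for tx, scale in (("SPIKE_FLUC", 480.0), ("SPIKE_RLUC", 4800.0)):
        counts[f"{tx}_mAUG"] = scale
        for i in range(1, 4):
            counts[f"{tx}_i{i}"] = scale / (2**i)
    return counts


def default_spike_reference() -> tuple[Annotations, dict[str, str], SpikeInReference]:
    """Fixed two-transcript spike set with a main AUG and 3 internal AUG
    counting categories each."""
    utr = "CCTTCCTTCCTTCCTTCCTT"  # 20 nt, no ATG
    annots = Annotations()
    seqs: dict[str, str] = {}
    categories: dict[str, tuple[str, int]] = {}
    for tx in ("SPIKE_FLUC", "SPIKE_RLUC"):
        cds = _spike_cds(n_iaugs=3)
        seq = utr + cds + "CCTTCC"
        cds_start = len(utr) + 1
        cds_end = len(utr) + len(cds)
        iaugs = []
        idx = cds.find("ATG", 3)
        while idx != -1:
            pos = cds_start + idx
            if pos >= cds_start + 8:
                iaugs.append(pos)
            idx = cds.find("ATG", idx + 3)
        annots.add(
            TranscriptAnnotation(
                transcript_id=tx,
                utr5_len=len(utr),
                cds_start=cds_start,
                cds_end=cds_end,
                tx_len=len(seq),
                internal_aug_positions=iaugs,
                is_spikein=True,
            )
        )
        seqs[tx] = seq
        categories[f"{tx}_mAUG"] = (tx, cds_start)
        for i, pos in enumerate(iaugs[:3], start=1):
            categories[f"{tx}_i{i}"] = (tx, pos)
    return annots, seqs, SpikeInReference(categories)


# ---------------------------------------------------------------------------
# transcriptome generation

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _find_augs(seq: str, start: int, end: int) -> list[int]:
    """1-based positions p in [start, end] with seq[p..p+2] == ATG (ATG fully
    inside [start, end+2] is the caller's concern; here p+2 <= end)."""
    out = []
    idx = seq.find("ATG", start - 1, end)
    while idx != -1:
        pos = idx + 1
        if pos + 2 <= end:
            out.append(pos)
        idx = seq.find("ATG", idx + 1, end)
    return out


@dataclass
class SyntheticDataset:
    """Everything one simulation run produces."""

    config: SyntheticConfig
    annots: Annotations          # toy transcriptome + spike transcripts
    sequences: dict[str, str]
    pars: pd.DataFrame           # transcript_id, position, score
    abundance: pd.Series
    truth: pd.DataFrame          # planted per-transcript ground truth
    spike_ref: SpikeInReference
    sample_loss: pd.Series
    footprints: pd.DataFrame | None = None   # all samples, incl. spikes
    rnaseq: pd.DataFrame | None = None

    def transcript_ids(self) -> list[str]:
        return [a.transcript_id for a in self.annots if not a.is_spikein]


def generate_transcriptome(config: SyntheticConfig, seed: int | None = None) -> SyntheticDataset:
    """Draw a toy transcriptome with sequences, structure profiles, context
    scores, abundances and planted ground truth (no footprints yet)."""
    master = config.seed if seed is None else seed
    rng = np.random.default_rng([master, _STAGE_TRANSCRIPTOME])
    n = config.n_transcripts
    ctx_model = ContextScoreModel.synthetic_default()

    spike_annots, spike_seqs, spike_ref = default_spike_reference()
    annots = Annotations()
    seqs: dict[str, str] = {}
    pars_rows: list[pd.DataFrame] = []

    if config.utr5_len_fixed is not None:
        utr5_lens = np.full(n, int(config.utr5_len_fixed))
    else:
        utr5_lens = np.round(rng.lognormal(config.utr5_len_log_mean, config.utr5_len_log_sd, size=n)).astype(int)
        utr5_lens = np.maximum(utr5_lens, 0)
    cds_lens = np.round(rng.lognormal(config.cds_len_log_mean, config.cds_len_log_sd, size=n)).astype(int)
    cds_lens = np.maximum((cds_lens // 3) * 3, config.cds_len_min)

    levels = rng.normal(config.pars_level_mean, config.pars_level_sd, size=n)
    max30 = np.zeros(n)
    context = np.full(n, np.nan)

    for i in range(n):
        tx = f"TX{i + 1:05d}"
        utr = _random_seq(rng, int(utr5_lens[i]))
        n_codons = cds_lens[i] // 3 - 2
        cds = "ATG" + _random_seq(rng, 3 * n_codons) + "TAA"
        utr3 = _random_seq(rng, config.utr3_len)
        seq = utr + cds + utr3
        cds_start = len(utr) + 1
        cds_end = len(utr) + len(cds)
        iaugs = [p for p in _find_augs(seq, cds_start + 3, cds_end) if p >= cds_start + 8]
        uaugs = _find_augs(seq, 1, len(utr)) if len(utr) >= 3 else []
        annot = TranscriptAnnotation(
            transcript_id=tx,
            utr5_len=len(utr),
            cds_start=cds_start,
            cds_end=cds_end,
            tx_len=len(seq),
            internal_aug_positions=iaugs,
            upstream_start_positions=uaugs,
        )
        annot.context_score = compute_context_score(seq, annot, ctx_model)
        scores = levels[i] + rng.normal(0.0, config.pars_nt_sd, size=len(seq))
        summaries = compute_pars_summaries(scores, annot)
        max30[i] = summaries["max30_pars"]
        context[i] = annot.context_score
        annots.add(annot)
        seqs[tx] = seq
        pars_rows.append(
            pd.DataFrame({"transcript_id": tx, "position": np.arange(1, len(seq) + 1), "score": scores})
        )

    for rec in spike_annots:
        annots.add(rec)
    seqs.update(spike_seqs)

    tx_ids = [f"TX{i + 1:05d}" for i in range(n)]
    abundance = pd.Series(
        rng.lognormal(0.0, config.abundance_log_sd, size=n), index=pd.Index(tx_ids, name="transcript_id"),
        name="abundance",
    )
    if n:
        abundance /= abundance.mean()

    truth = _compute_truth(config, annots, abundance, max30, context, rng)
    pars = (
        pd.concat(pars_rows, ignore_index=True)
        if pars_rows
        else pd.DataFrame(columns=["transcript_id", "position", "score"])
    )

    loss_rng = np.random.default_rng([master, _STAGE_LOSSES])
    samples = config.sample_names()
    if config.sample_loss is not None:
        loss = pd.Series({s: float(config.sample_loss[s]) for s in samples}, name="loss")
    else:
        draws = np.exp(loss_rng.uniform(np.log(0.25), np.log(1.0), size=len(samples)))
        loss = pd.Series(draws, index=samples, name="loss")
    if ((loss <= 0) | (loss > 1)).any():
        raise ValueError("sample losses must lie in (0, 1]")

    return SyntheticDataset(
        config=config,
        annots=annots,
        sequences=seqs,
        pars=pars,
        abundance=abundance,
        truth=truth,
        spike_ref=spike_ref,
        sample_loss=loss,
    )


def _compute_truth(
    config: SyntheticConfig,
    annots: Annotations,
    abundance: pd.Series,
    max30: np.ndarray,
    context: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    tx_ids = list(abundance.index)
    n = len(tx_ids)
    utr5 = np.array([annots[t].utr5_len for t in tx_ids], dtype=float)
    penalty = config.penalty_alpha * np.maximum(max30, 0.0) + config.penalty_beta * utr5
    base_weight = np.exp(-penalty)

    if config.stim_mode == "penalty":
        S = config.stim_scale * penalty
    elif config.stim_mode == "uniform":
        S = np.full(n, config.stim_base)
    else:  # flagged
        S = np.zeros(n)
        n_stim = int(round(config.stim_frac * n))
        stim_idx = rng.choice(n, size=n_stim, replace=False) if n_stim else np.array([], dtype=int)
        S[stim_idx] = config.stim_S

    ctx_term = np.where(np.isfinite(context), 1.0 - context, 1.0)
    leak_flagged = np.zeros(n, dtype=bool)
    if config.leak_mode == "flagged":
        n_leaky = int(round(config.leak_planted_frac * n))
        if n_leaky:
            leak_flagged[rng.choice(n, size=n_leaky, replace=False)] = True

    truth = pd.DataFrame(
        {
            "abundance": abundance.to_numpy(),
            "max30_pars": max30,
            "utr5_len": utr5.astype(int),
            "context_score": context,
            "penalty": penalty,
            "base_weight": base_weight,
            "stim_S": S,
            "is_leaky_planted": leak_flagged,
        },
        index=pd.Index(tx_ids, name="transcript_id"),
    )

    has_uaug = np.array([len(annots[t].upstream_start_positions) > 0 for t in tx_ids])
    has_iaug = np.array([len(annots[t].internal_aug_positions) > 0 for t in tx_ids])
    uaug_p = np.where(has_uaug, config.uaug_init_prob, 0.0)
    truth["uaug_prob"] = uaug_p

    # fraction of mAUG footprints whose (length, 5'-offset) combination fits
    # inside the transcript; out-of-bounds events are skipped at simulation
    observable = np.ones(n)
    for j, t in enumerate(tx_ids):
        a = annots[t]
        frac = 0.0
        for ln, pl in config.footprint_len_probs.items():
            for off, po in config.offset_jitter_probs.items():
                five = a.cds_start + off
                if five >= 1 and five + ln - 1 <= a.tx_len:
                    frac += pl * po
        observable[j] = frac
    truth["mrpf_observable"] = observable

    for ci, cond in enumerate(config.condition_names):
        conc = config.ded1_concs[ci]
        f = conc / (conc + config.ded1_K) if conc > 0 else 0.0
        stim = 1.0 + S * f
        weight = abundance.to_numpy() * base_weight * stim
        if config.leak_mode == "context":
            leak = np.clip((config.leak_base + config.leak_context_slope * ctx_term) * config.leak_ded1_mult[ci], 0.0, 1.0)
        else:
            later = ci > 0
            leak = np.where(leak_flagged & later, config.leak_high, config.leak_base)
        # leaked events that find no internal AUG are lost, not re-assigned
        truth[f"weight_{cond}"] = weight
        truth[f"stim_factor_{cond}"] = stim
        truth[f"leak_prob_{cond}"] = leak
        share = weight / weight.sum() if n and weight.sum() > 0 else np.zeros(n)
        exp_mrpf = config.pic_pool * share * (1.0 - uaug_p) * (1.0 - leak) * observable
        density = abundance.to_numpy() * config.rnaseq_reads_per_nt
        with np.errstate(divide="ignore", invalid="ignore"):
            exp_re = np.where(density > 0, exp_mrpf / density, np.nan)
        truth[f"expected_mrpf_{cond}"] = exp_mrpf
        truth[f"expected_re_{cond}"] = exp_re

    top = config.condition_names[-1]
    truth["is_ded1_stimulated"] = truth[f"stim_factor_{top}"] >= config.stim_call_threshold
    truth["has_iaug"] = has_iaug
    # a planted leak shift is only observable as an mRPF->iRPF transfer when
    # the transcript actually has an internal AUG to initiate on
    truth["is_leaky_planted"] = truth["is_leaky_planted"] & has_iaug
    return truth


# ---------------------------------------------------------------------------
# recruitment weights


def compute_recruitment_weights(
    truth: pd.DataFrame, ded1_conc: float, config: SyntheticConfig
) -> pd.Series:
    """weight = abundance * base_weight * (1 + S * conc/(conc+K))."""
    if ded1_conc < 0:
        raise ValueError("helicase concentration must be >= 0")
    f = ded1_conc / (ded1_conc + config.ded1_K) if ded1_conc > 0 else 0.0
    w = truth["abundance"] * truth["base_weight"] * (1.0 + truth["stim_S"] * f)
    w.name = "weight"
    return w


# ---------------------------------------------------------------------------
# footprint simulation


def _geometric_alloc(rng: np.random.Generator, n_events: int, n_sites: int, stop: float, allow_loss: bool) -> np.ndarray:
    """Allocate events over ordered sites with a geometric stop rule.

    Site j (0-based) has probability stop*(1-stop)^j; with ``allow_loss`` the
    residual mass (1-stop)^n_sites is a lost category appended at the end,
    otherwise probabilities are renormalized over the sites.
    """
    if n_sites == 0:
        return np.array([n_events] if allow_loss else [], dtype=int)
    probs = stop * (1.0 - stop) ** np.arange(n_sites)
    if allow_loss:
        probs = np.append(probs, (1.0 - stop) ** n_sites)
    else:
        probs = probs / probs.sum()
    return rng.multinomial(n_events, probs)


def _emit_site_counts(
    rng: np.random.Generator,
    config: SyntheticConfig,
    sample_id: str,
    tx: str,
    tx_len: int,
    site_counts: dict[int, int],
    scale: float,
    rows: list[tuple],
    skipped: dict[str, int],
) -> None:
    """Apply count noise and expand AUG-site counts into footprint rows."""
    lens = np.array(sorted(config.footprint_len_probs))
    len_p = np.array([config.footprint_len_probs[l] for l in lens])
    offs = np.array(sorted(config.offset_jitter_probs))
    off_p = np.array([config.offset_jitter_probs[o] for o in offs])
    combo_p = np.outer(len_p, off_p).ravel()
    combo_p = combo_p / combo_p.sum()

    for aug_pos, n_events in site_counts.items():
        if n_events <= 0:
            continue
        if config.count_noise == "none":
            c = int(round(n_events * scale))
        else:
            c = int(rng.poisson(n_events * scale))
        if c <= 0:
            continue
        alloc = rng.multinomial(c, combo_p).reshape(len(lens), len(offs))
        for li, ln in enumerate(lens):
            for oi, off in enumerate(offs):
                cnt = int(alloc[li, oi])
                if cnt == 0:
                    continue
                five = aug_pos + int(off)
                if five < 1 or five + int(ln) - 1 > tx_len:
                    skipped["out_of_bounds"] = skipped.get("out_of_bounds", 0) + cnt
                    continue
                rows.append((sample_id, tx, five, int(ln), cnt))


def simulate_footprints(
    dataset: SyntheticDataset,
    condition: str,
    sample_id: str,
    seed: int | None = None,
    skipped: dict | None = None,
) -> pd.DataFrame:
    """Simulate one sample's footprints on the toy transcriptome.

    The full pool is allocated multinomially by recruitment weight; each
    initiation event picks an upstream start (prob ``uaug_prob``), else the
    main AUG unless it reads through (planted leak prob), in which case the
    first downstream internal AUG under a geometric stop rule (events that
    exhaust the internal AUG list are lost).  Sample loss and count noise
    are applied per site, then lengths and 5'-end offsets are drawn.
    """
    config = dataset.config
    if condition not in config.condition_names:
        raise KeyError(f"unknown condition {condition!r}")
    master = config.seed if seed is None else seed
    sample_idx = config.sample_names().index(sample_id)
    rng = np.random.default_rng([master, _STAGE_FOOTPRINTS, sample_idx])
    loss = float(dataset.sample_loss[sample_id])

    tx_ids = dataset.transcript_ids()
    truth = dataset.truth
    weights = truth[f"weight_{condition}"].to_numpy(dtype=float)
    leak = truth[f"leak_prob_{condition}"].to_numpy(dtype=float)
    uaug_p = truth["uaug_prob"].to_numpy(dtype=float)

    rows: list[tuple] = []
    skipped = skipped if skipped is not None else {}
    if config.pic_pool > 0 and len(tx_ids) and weights.sum() > 0:
        alloc = rng.multinomial(config.pic_pool, weights / weights.sum())
        # gamma multiplier gives NB overdispersion at the transcript level
        if config.count_noise == "nb" and config.nb_dispersion > 0:
            shape = 1.0 / config.nb_dispersion
            gammas = rng.gamma(shape, 1.0 / shape, size=len(tx_ids))
        else:
            gammas = np.ones(len(tx_ids))
        for i, tx in enumerate(tx_ids):
            n_i = int(alloc[i])
            if n_i == 0:
                continue
            annot = dataset.annots[tx]
            n_u = rng.binomial(n_i, uaug_p[i]) if uaug_p[i] > 0 else 0
            n_rest = n_i - n_u
            n_leak = rng.binomial(n_rest, leak[i]) if leak[i] > 0 else 0
            n_main = n_rest - n_leak

            site_counts: dict[int, int] = {}
            if n_main:
                site_counts[annot.cds_start] = site_counts.get(annot.cds_start, 0) + n_main
            if n_u:
                ualloc = _geometric_alloc(rng, n_u, len(annot.upstream_start_positions), config.leak_stop_prob, allow_loss=False)
                for pos, cnt in zip(annot.upstream_start_positions, ualloc):
                    if cnt:
                        site_counts[pos] = site_counts.get(pos, 0) + int(cnt)
            if n_leak:
                ialloc = _geometric_alloc(rng, n_leak, len(annot.internal_aug_positions), config.leak_stop_prob, allow_loss=True)
                for pos, cnt in zip(annot.internal_aug_positions, ialloc[: len(annot.internal_aug_positions)]):
                    if cnt:
                        site_counts[pos] = site_counts.get(pos, 0) + int(cnt)
                lost = int(ialloc[-1])
                if lost:
                    skipped["leak_lost"] = skipped.get("leak_lost", 0) + lost
            _emit_site_counts(rng, config, sample_id, tx, annot.tx_len, site_counts, loss * gammas[i], rows, skipped)

    df = make_footprint_frame(rows)
    return df.groupby(FOOTPRINT_COLUMNS[:-1], as_index=False)["count"].sum() if len(df) else df


def simulate_spikeins(
    dataset: SyntheticDataset, sample_id: str, seed: int | None = None
) -> pd.DataFrame:
    """Constant spike complexes scaled by the sample's loss factor."""
    config = dataset.config
    master = config.seed if seed is None else seed
    sample_idx = config.sample_names().index(sample_id)
    rng = np.random.default_rng([master, _STAGE_SPIKES, sample_idx])
    loss = float(dataset.sample_loss[sample_id])

    rows: list[tuple] = []
    skipped: dict[str, int] = {}
    for label, expected in config.spike_counts.items():
        tx, aug_pos = dataset.spike_ref.categories[label]
        annot = dataset.annots[tx]
        mean = expected * loss
        site = {aug_pos: 1}
        # reuse the noise/emission path with the site count folded into scale
        _emit_site_counts(rng, config, sample_id, tx, annot.tx_len, site, mean, rows, skipped)
    df = make_footprint_frame(rows)
    return df.groupby(FOOTPRINT_COLUMNS[:-1], as_index=False)["count"].sum() if len(df) else df


def simulate_rnaseq(
    dataset: SyntheticDataset, sample_id: str = "rnaseq", seed: int | None = None
) -> pd.DataFrame:
    """Uniform fragment 5'-end positions; reads per transcript proportional to
    abundance x length.  Columns: sample_id, transcript_id, position, count."""
    config = dataset.config
    master = config.seed if seed is None else seed
    rng = np.random.default_rng([master, _STAGE_RNASEQ])
    frames = []
    for tx in dataset.transcript_ids():
        annot = dataset.annots[tx]
        mean = dataset.abundance[tx] * config.rnaseq_reads_per_nt * annot.tx_len
        if config.count_noise == "none":
            n = int(round(mean))
            if n == 0:
                continue
            # deterministic near-uniform coverage
            pos = (np.arange(n) % annot.tx_len) + 1
        else:
            n = int(rng.poisson(mean))
            if n == 0:
                continue
            pos = rng.integers(1, annot.tx_len + 1, size=n)
        uniq, cnt = np.unique(pos, return_counts=True)
        frames.append(
            pd.DataFrame({"sample_id": sample_id, "transcript_id": tx, "position": uniq, "count": cnt})
        )
    if not frames:
        return pd.DataFrame(columns=["sample_id", "transcript_id", "position", "count"])
    return pd.concat(frames, ignore_index=True)


def simulate_dataset(config: SyntheticConfig, seed: int | None = None) -> SyntheticDataset:
    """Full run: transcriptome, per-sample footprints + spikes, RNA-seq."""
    master = config.seed if seed is None else seed
    ds = generate_transcriptome(config, seed=master)
    conditions = config.sample_conditions()
    frames = []
    for sample in config.sample_names():
        fp = simulate_footprints(ds, conditions[sample], sample, seed=master)
        sp = simulate_spikeins(ds, sample, seed=master)
        frames.extend([fp, sp])
    ds.footprints = pd.concat([f for f in frames if len(f)], ignore_index=True) if frames else make_footprint_frame()
    ds.rnaseq = simulate_rnaseq(ds, seed=master)
    return ds


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write all dataset tables as plain text; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotations": outdir / "annotations.tsv",
        "transcriptome": outdir / "transcriptome.fasta",
        "pars": outdir / "pars.tsv",
        "abundance": outdir / "abundance.tsv",
        "truth": outdir / "truth.tsv",
        "spike_ref": outdir / "spike_ref.tsv",
        "samples": outdir / "samples.tsv",
        "config": outdir / "config.yaml",
    }
    ds.annots.to_tsv(paths["annotations"])
    write_fasta(ds.sequences, paths["transcriptome"])
    ds.pars.to_csv(paths["pars"], sep="\t", index=False)
    ds.abundance.rename_axis("transcript_id").reset_index().to_csv(paths["abundance"], sep="\t", index=False)
    ds.truth.reset_index().to_csv(paths["truth"], sep="\t", index=False)
    ds.spike_ref.to_tsv(paths["spike_ref"])
    samples = pd.DataFrame(
        {
            "sample_id": ds.config.sample_names(),
            "condition": [ds.config.sample_conditions()[s] for s in ds.config.sample_names()],
            "loss": [ds.sample_loss[s] for s in ds.config.sample_names()],
        }
    )
    samples.to_csv(paths["samples"], sep="\t", index=False)
    ds.config.to_yaml(paths["config"])
    if ds.footprints is not None:
        paths["footprints"] = outdir / "footprints.tsv"
        ds.footprints.to_csv(paths["footprints"], sep="\t", index=False)
    if ds.rnaseq is not None:
        paths["rnaseq"] = outdir / "rnaseq.tsv"
        ds.rnaseq.to_csv(paths["rnaseq"], sep="\t", index=False)
    return paths
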