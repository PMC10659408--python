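import numpy as np
import pandas as pd
import pytest

from recseq.psite_counting import PsiteConfig, count_regions
from recseq.synthetic_data import (
    SyntheticConfig,
    compute_recruitment_weights,
    generate_transcriptome,
    simulate_dataset,
    simulate_footprints,
    simulate_rnaseq,
)


def _cfg(**kw):
    defaults = dict(n_transcripts=20, pic_pool=20_000, seed=1)
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestConfigValidation:
    def test_bad_probability_vector(self):
        with pytest.raises(ValueError, match="sums"):
            _cfg(footprint_len_probs={28: 0.5, 29: 0.4})

    def test_length_out_of_range(self):
        with pytest.raises(ValueError, match="25"):
            _cfg(footprint_len_probs={24: 1.0})

    def test_leak_prob_bounds(self):
        with pytest.raises(ValueError):
            _cfg(leak_base=1.5)

    def test_mult_per_condition(self):
        with pytest.raises(ValueError):
            _cfg(leak_ded1_mult=(1.0,))

    def test_yaml_roundtrip(self, tmp_path):
        cfg = _cfg(leak_base=0.1, offset_jitter_probs={-12: 0.8, -11: 0.2})
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SyntheticConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg


class TestGenerateTranscriptome:
    def test_zero_transcripts(self):
        ds = generate_transcriptome(_cfg(n_transcripts=0))
        assert ds.transcript_ids() == []

    def test_fixed_zero_utr(self):
        ds = generate_transcriptome(_cfg(utr5_len_fixed=0))
        for tx in ds.transcript_ids():
            a = ds.annots[tx]
            assert a.cds_start == 1
            assert a.upstream_start_positions == []

    def test_cds_starts_with_aug_ends_with_stop(self):
        ds = generate_transcriptome(_cfg())
        for tx in ds.transcript_ids():
            a = ds.annots[tx]
            seq = ds.sequences[tx]
            assert seq[a.cds_start - 1 : a.cds_start + 2] == "ATG"
            assert seq[a.cds_end - 3 : a.cds_end] in ("TAA", "TAG", "TGA")

    def test_augs_annotated_from_sequence(self):
        ds = generate_transcriptome(_cfg(seed=4))
        for tx in ds.transcript_ids():
            a = ds.annots[tx]
            seq = ds.sequences[tx]
            for p in a.internal_aug_positions:
                assert seq[p - 1 : p + 2] == "ATG"
                assert p >= a.cds_start + 8  # signed position >= +9
            for p in a.upstream_start_positions:
                assert seq[p - 1 : p + 2] == "ATG"
                assert p + 2 <= a.utr5_len

    def test_determinism_byte_identical_tables(self, tmp_path):
        a = generate_transcriptome(_cfg(seed=77))
        b = generate_transcriptome(_cfg(seed=77))
        a.annots.to_tsv(tmp_path / "a.tsv")
        b.annots.to_tsv(tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
        pd.testing.assert_frame_equal(a.truth, b.truth)


class TestRecruitmentWeights:
    def test_no_penalty_means_conc_independent(self):
        cfg = _cfg(penalty_alpha=0.0, penalty_beta=0.0, stim_mode="penalty")
        ds = generate_transcriptome(cfg)
        w0 = compute_recruitment_weights(ds.truth, 0.0, cfg)
        w500 = compute_recruitment_weights(ds.truth, 500.0, cfg)
        assert np.allclose(w0, w500)

    def test_half_saturation_identity(self):
        cfg = _cfg()
        ds = generate_transcriptome(cfg)
        wK = compute_recruitment_weights(ds.truth, cfg.ded1_K, cfg)
        want = ds.truth["abundance"] * ds.truth["base_weight"] * (1 + ds.truth["stim_S"] / 2)
        assert np.allclose(wK, want)

    def test_monotone_in_concentration(self):
        cfg = _cfg()
        ds = generate_transcriptome(cfg)
        prev = compute_recruitment_weights(ds.truth, 0.0, cfg)
        for conc in (10.0, 100.0, 1000.0):
            cur = compute_recruitment_weights(ds.truth, conc, cfg)
            assert (cur >= prev - 1e-12).all()
            prev = cur

    def test_structured_transcript_lower_base_higher_stim(self):
        # evaluate the formula directly on two synthetic rows
        cfg = _cfg(penalty_beta=0.0, penalty_alpha=0.05, stim_mode="penalty", stim_scale=1.0)
        truth = pd.DataFrame(
            {
                "abundance": [1.0, 1.0],
                "base_weight": np.exp(-0.05 * np.array([10.0, 20.0])),
                "stim_S": 1.0 * 0.05 * np.array([10.0, 20.0]),
            },
            index=["plain", "structured"],
        )
        w0 = compute_recruitment_weights(truth, 0.0, cfg)
        w = compute_recruitment_weights(truth, 500.0, cfg)
        assert truth.loc["structured", "base_weight"] < truth.loc["plain", "base_weight"]
        assert (w / w0)["structured"] > (w / w0)["plain"]

    def test_negative_concentration_rejected(self):
        cfg = _cfg()
        ds = generate_transcriptome(cfg)
        with pytest.raises(ValueError):
            compute_recruitment_weights(ds.truth, -1.0, cfg)


class TestSimulateFootprints:
    def test_pool_zero_empty(self):
        ds = generate_transcriptome(_cfg(pic_pool=0))
        fp = simulate_footprints(ds, "ded1_0", "ded1_0_r1")
        assert len(fp) == 0

    def test_jitter_free_all_at_minus12(self):
        cfg = _cfg(
            leak_base=0.0,
            uaug_init_prob=0.0,
            utr5_len_log_mean=4.0,
            utr5_len_log_sd=0.2,
            count_noise="none",
            sample_loss=None,
        )
        ds = generate_transcriptome(cfg)
        fp = simulate_footprints(ds, "ded1_0", "ded1_0_r1")
        starts = {ds.annots[tx].cds_start for tx in fp["transcript_id"]}
        for row in fp.itertuples(index=False):
            assert row.five_prime_pos == ds.annots[row.transcript_id].cds_start - 12

    def test_pool_conserved_without_noise_or_loss(self):
        samples = {f"ded1_{c}_r{i+1}": 1.0 for c in ("0", "500") for i in range(3)}
        cfg = _cfg(
            leak_base=0.0,
            uaug_init_prob=0.0,
            utr5_len_fixed=40,
            count_noise="none",
            sample_loss=samples,
            pic_pool=5_000,
        )
        ds = generate_transcriptome(cfg)
        fp = simulate_footprints(ds, "ded1_0", "ded1_0_r1")
        assert fp["count"].sum() == cfg.pic_pool

    def test_forced_leak_lands_on_first_iaug(self):
        cfg = _cfg(
            leak_base=1.0,
            leak_stop_prob=1.0,
            uaug_init_prob=0.0,
            utr5_len_fixed=40,
            count_noise="none",
        )
        ds = generate_transcriptome(cfg)
        fp = simulate_footprints(ds, "ded1_0", "ded1_0_r1")
        for row in fp.itertuples(index=False):
            a = ds.annots[row.transcript_id]
            assert a.internal_aug_positions, "leak requires an internal AUG"
            assert row.five_prime_pos == a.internal_aug_positions[0] - 12

    def test_bounds_respected(self, small_dataset):
        fp = small_dataset.footprints
        for row in fp.itertuples(index=False):
            tx_len = small_dataset.annots[row.transcript_id].tx_len
            assert 1 <= row.five_prime_pos
            assert row.five_prime_pos + row.length - 1 <= tx_len

    def test_unknown_condition_rejected(self):
        ds = generate_transcriptome(_cfg())
        with pytest.raises(KeyError):
            simulate_footprints(ds, "nope", "ded1_0_r1")


class TestSimulateRnaseq:
    def test_zero_abundance_zero_reads(self):
        cfg = _cfg(n_transcripts=3)
        ds = generate_transcriptome(cfg)
        ds.abundance[:] = 0.0
        assert len(simulate_rnaseq(ds)) == 0

    def test_reads_scale_with_cds_length_not_density(self):
        cfg = _cfg(n_transcripts=30, count_noise="none", utr3_len=0, utr5_len_fixed=0, rnaseq_reads_per_nt=2.0)
        ds = generate_transcriptome(cfg)
        ds.abundance[:] = 1.0
        reads = simulate_rnaseq(ds)
        per_tx = reads.groupby("transcript_id")["count"].sum()
        for tx in ds.transcript_ids():
            tx_len = ds.annots[tx].tx_len
            assert per_tx[tx] == pytest.approx(2.0 * tx_len, rel=0.01)

    def test_determinism(self):
        cfg = _cfg()
        ds = generate_transcriptome(cfg)
        r1 = simulate_rnaseq(ds)
        r2 = simulate_rnaseq(ds)
        pd.testing.assert_frame_equal(r1, r2)


class TestFullSimulationDeterminism:
    def test_bitwise_reproducible(self):
        cfg = _cfg(n_transcripts=15, pic_pool=10_000, seed=99)
        d1 = simulate_dataset(cfg)
        d2 = simulate_dataset(cfg)
        pd.testing.assert_frame_equal(d1.footprints, d2.footprints)
        pd.testing.assert_frame_equal(d1.rnaseq, d2.rnaseq)
        pd.testing.assert_series_equal(d1.sample_loss, d2.sample_loss)

    def test_seed_changes_output(self):
        d1 = simulate_dataset(_cfg(seed=1))
        d2 = simulate_dataset(_cfg(seed=2))
        assert not d1.footprints.equals(d2.footprints)


class TestPlantedDeltaRecovery:
    def test_planted_delta_re_recovered_noiselessly(self):
        # deep, noiseless, uniform 3-fold stimulation: planted dRE equals the
        # ratio of expected weights up to multinomial sampling error
        samples = {f"ded1_{c}_r{i+1}": 1.0 for c in ("0", "500") for i in range(3)}
        cfg = _cfg(
            n_transcripts=30,
            pic_pool=400_000,
            stim_mode="uniform",
            stim_base=10.0,
            ded1_K=100.0,
            leak_base=0.0,
            uaug_init_prob=0.0,
            utr5_len_fixed=40,
            count_noise="none",
            sample_loss=samples,
            rnaseq_reads_per_nt=2.0,
            seed=12,
        )
        ds = simulate_dataset(cfg)
        from recseq.pipeline_cli import analyze_dataset

        out = analyze_dataset(ds, regions=("mRPF",), min_total=0)
        re = out["re"].dropna()
        got = (re["ded1_500"] / re["ded1_0"]).median()
        want = (
            ds.truth["expected_re_ded1_500"] / ds.truth["expected_re_ded1_0"]
        ).median()
        assert got == pytest.approx(want, rel=0.02)
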