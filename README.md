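# recseq

Analysis of 48S pre-initiation-complex (PIC) footprint data in transcript
coordinates: P-site assignment and region counting, spike-in geometric-mean
normalization, negative-binomial differential recruitment testing,
recruitment-efficiency (RE) and relative-ribosome-occupancy (RRO) metrics,
structure/context feature analysis, and reciprocal leaky-scanning /
upstream-initiation classification.  A matched synthetic-data generator
emulates the generative process the analysis assumes, so every stage is
testable without any external data.

## Layout

| module | what it does |
| --- | --- |
| `recseq.synthetic_data` | toy transcriptome + multi-sample footprint/RNA-seq simulator with planted effects, spike-ins, NB noise |
| `recseq.psite_counting` | P-site offsets, mRPF/uRPF/iRPF/cdsRPF window counting, metagene matrices, wiggle tracks |
| `recseq.spike_norm` | spike-in category counting, geometric-mean size factors, normalization |
| `recseq.differential` | min-count filtering, dispersion estimation, two-group NB Wald test, BH, significance classes, hypergeometric overlaps, Spearman |
| `recseq.efficiency` | mRNA density, RE, RRO, between-condition deltas, uRPF/mRPF totals |
| `recseq.feature_analysis` | structure-score (PARS-like) window summaries, start-codon context scores, equal-size binning, reciprocity classifiers |
| `recseq.pipeline_cli` | `recseq` CLI, input validation, end-to-end orchestration with manifests |

Coordinates are 1-based along transcripts; signed positions relative to the
main AUG use A-of-AUG = +1 with no position 0.  Counting windows (closed,
signed): mRPF `[-3, +6]`, iRPF `[+9, stop end]`, cdsRPF `[-3, stop end]`,
uRPF `[5' end, -5]`.  The default P-site offset is +12 nt from the 5' end
for all 25-34 nt footprints.

## CLI

```bash
recseq simulate --outdir sim --seed 1            # synthetic dataset (TSV/FASTA/YAML)
recseq count --footprints sim/footprints.tsv --annotations sim/annotations.tsv --out counts.tsv
recseq normalize --footprints sim/footprints.tsv --spike-ref sim/spike_ref.tsv --out sf.tsv
recseq diffexp --counts counts.tsv --size-factors sf.tsv --samples sim/samples.tsv \
    --contrast ded1_500:ded1_0 --region mRPF --min-total 90 --out diff.tsv
recseq efficiency --counts counts.tsv --size-factors sf.tsv --samples sim/samples.tsv \
    --annotations sim/annotations.tsv --rnaseq sim/rnaseq.tsv --pairs ded1_500:ded1_0 --out eff.tsv
recseq metagene --footprints sim/footprints.tsv --annotations sim/annotations.tsv --out metagene.tsv
recseq tracks --footprints sim/footprints.tsv --annotations sim/annotations.tsv --out tracks.wig
recseq features --pars sim/pars.tsv --annotations sim/annotations.tsv --out pars_summaries.tsv
recseq run --config run.yaml                     # validate + full pipeline + manifest
```

`recseq run` takes a YAML file with the fields of
`recseq.pipeline_cli.RunConfig` (paths, condition design, contrasts,
thresholds).  Exit code 2 marks validation failures, 1 runtime failures.

## Statistical notes

The differential module is an owned, simplified NB pipeline, not a DESeq2
wrapper: method-of-moments per-gene dispersions, a robust `a0 + a1/mean`
trend, log-space shrinkage toward the trend, exact NB group-mean MLEs, and
a Wald test with expected-information standard errors referred to a mildly
heavy-tailed t distribution (df = 8 x residual df) for small-sample tail
calibration.  There is no Cook's outlier filtering, independent filtering,
or LFC shrinkage; size factors always come from spike-ins and are never
re-estimated from transcriptome counts.
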