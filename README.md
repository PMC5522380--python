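# accessmask

Genome **accessibility masks** and alignment depth / mapping-quality QC from
multi-sample short-read pileups.

When thousands of low-coverage genomes are aligned to a reference assembly,
only part of the assembly supports reliable variant calling: regions of
anomalous summed coverage, or dominated by multi-mapping reads, produce
unreliable calls. `accessmask` reimplements, as a tested reusable pipeline,
the classic pilot/strict accessibility-mask construction used for
population-scale archives, together with the per-chromosome coverage and
mapping-quality summaries used to sanity-check such alignments. It is aimed
at people building or validating multi-sample alignment sets who want
callable-region tracks and the QC numbers behind them.

## The model

Per reference position the pipeline aggregates three numbers across all
samples: total read depth *d*, the count of mapping-quality-0 reads *z*
(MQ0: reads mapping equally well to several places), and the sum of mapping
qualities *s*. From the autosomal mean depth *m* (computed over non-N
autosomal sites) each profile resolves to absolute cutoffs, and every base
gets exactly one category, tested in fixed precedence:

| code | rule |
|------|------|
| `N` | reference base is N |
| `L` | *d* < 0.5·*m* |
| `H` | *d* > 2·*m* (pilot) or *d* > 1.5·*m* (strict) |
| `Z` | *z*/*d* > 20% (pilot) or *z*/*d* ≥ 0.1% (strict) |
| `Q` | *s*/*d* below the autosomal read-weighted mean MQ (strict only) |
| `P` | passed — the site is accessible |

Depth bounds are inclusive. For a cohort with autosomal mean total depth
20,360× these rules give the pilot window 10,180×–40,720× and the strict
window 10,180×–30,540×. The expected non-pseudoautosomal sex-chromosome
depths follow from copy numbers: with female fraction *f*,
E[X] = *m*·(2*f* + (1−*f*))/2 and E[Y] = *m*·(1−*f*)/2 — about ¾ and ¼ of
the autosomal depth for a balanced cohort.

A synthetic-data module generates toy references and multi-sample pileups
(or actual SAM read streams) with planted N-gaps, coverage dropouts and
pileups, and MQ0-shedding repeat regions, together with the model-implied
expected category of every base, so mask recovery can be tested end to end.
A small quality-binning module applies the lossy Illumina-style 8-level
quality reduction used before CRAM archiving.

## Worked example

Simulate the default 1 Mb toy cohort (10 samples at 8×, two autosomes plus
chrX/chrY at sex ratio 51:49, one planted region of each kind), then build
both masks:

```bash
accessmask simulate --out-dir sim --seed 42 --no-sam
accessmask mask --stats sim/stats.tsv --reference sim/reference.fa \
    --profile pilot --profile strict --out-dir mask
accessmask summarize --stats sim/stats.tsv --reference sim/reference.fa \
    --histogram-chromosome chrY --bin-width 5 --out-dir summ
```

`mask/summary.pilot.tsv`:

```
#profile=pilot
#scope  N       L       H       Z       Q       P       total_bases
genome  3.00%   12.11%  2.00%   3.50%   0.00%   79.39%  1000000
chr1    5.00%   5.00%   5.00%   5.00%   0.00%   80.00%  400000
chr2    3.33%   0.00%   0.00%   5.00%   0.00%   91.67%  300000
chrX    0.00%   0.54%   0.00%   0.00%   0.00%   99.46%  200000
chrY    0.00%   100.00% 0.00%   0.00%   0.00%   0.00%   100000
```

The planted regions come back as the 5% N/L/H/Z blocks on chr1; chrY is
entirely `L` because its expected depth — 24.5% of the autosomal mean with
51% females — sits below the 50% low bound, exactly as the depth model
predicts. `summ/expected_sex_depth.tsv` shows the expectation next to the
realized autosomal mean (82.85×):

```
#autosomal_mean  female_fraction  expected_X  expected_Y
82.8516          0.51             62.5530     20.2986
```

The mask run's `mask.manifest.json` records the derived thresholds (e.g.
pilot window 41.43×–165.70× from the realized mean), so every cutoff used is
reconstructible from the artifacts.

## Layout

- `accessmask.simulate` — synthetic cohorts with planted ground truth
- `accessmask.pileup` — streaming per-site depth/MQ0/MQ-sum accumulation,
  track merging, per-site TSV dialect
- `accessmask.mask` — profiles, threshold derivation, six-way
  classification, mask FASTA/BED/summary output
- `accessmask.coverage` — per-chromosome summaries, coverage histograms,
  expected sex-chromosome depth
- `accessmask.qualbin` — lossy quality-score binning
- `accessmask.cli` — `accessmask simulate | pileup | mask | summarize | binq`

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
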