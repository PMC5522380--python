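# Methods

## Site statistics and coordinate conventions

The pipeline's unit of information is the per-reference-position triple
(depth, MQ0 count, MQ sum) aggregated over every sample. Accumulation is a
single pass over alignment records into dense per-chromosome int64 arrays;
a read covers the positions its CIGAR aligns (M/=/X always, D-spanned
positions by default, N-skipped never). The default read filter drops
unmapped, secondary, supplementary, duplicate-flagged and QC-fail records
and keeps every MAPQ including 0 — the MQ0-fraction criterion needs the MQ0
reads in its own denominator, and they contribute 0 to the MQ sum.
Duplicate exclusion is a switch because archive pipelines commonly mark
duplicates without removing them, and either convention is defensible for
depth; the default (exclude) matches ordinary depth semantics.

Positions are 1-based inclusive at the SAM-facing surface and in the
per-site TSV; all BED output is 0-based half-open. Arrays are 0-indexed
internally (position *p* at index *p*−1).

## Mask profiles and classification

Category precedence is fixed as N > L > H > Z > Q > P. The six categories
are mutually exclusive and total; the footnote-order precedence is a design
choice — any site failing several criteria is reported under the first.
Boundary semantics, chosen from the rules' phrasing:

- depth bounds pass inclusively at both ends ("between X and Y");
- the pilot MQ0 rule passes at exactly 20% ("20% or fewer");
- the strict MQ0 rule fails at exactly 0.1% ("fewer than 0.1%");
- the strict average-MQ rule passes at exactly the cutoff ("average or
  higher").

Thresholds are kept as exact reals — no rounding — so an integer mean
reproduces printed bounds exactly (mean 20,360 → 10,180 / 40,720 / 30,540).
A non-N site with depth 0 classifies as L before any fraction is formed, so
0/0 never arises.

Two open choices are resolved as follows and exposed as parameters:
the anchoring mean depth is computed over **non-N autosomal** sites (N runs
carry no alignment signal and would dilute the mean; decoy/ALT contigs
should be excluded from both the mean and the mask because ALT
multi-mapping corrupts the MQ0 statistic); and the site-average mapping
quality is **read-weighted** (mq_sum/depth), as is the autosomal cutoff the
strict profile compares against (Σ mq_sum / Σ depth). The strict cutoff is
recomputed from the supplied track by default, with a `--avg-mq-cutoff`
override to pin it (e.g. 56) for reproduction runs.

## Expected sex-chromosome depth

With female fraction *f* and autosomal mean *m*, the expected non-PAR
depths are E[X] = *m*(2*f* + (1−*f*))/2 and E[Y] = *m*(1−*f*)/2: linear in
*m*, monotone in *f*, and equal to ¾*m* and ¼*m* at *f* = 0.5. The default
*f* is 0.51. Pseudoautosomal intervals are accepted by the simulator
(diploid in everyone) but default to empty; the expectation model addresses
the non-PAR portion only.

## The synthetic cohort

The simulator emulates the statistical regime the mask analysis assumes,
not reads themselves: per-site total depth is Poisson with rate
(sample count × per-sample depth × region multiplier × sex copy factor) —
a sum of per-sample Poissons is Poisson, so sampling once per site is
exact under the model. The MQ0 count is Binomial(depth, p) with p = 0.5 in
planted repeat regions and a background ε = 0.001 elsewhere (ε is a free
simulator parameter, not an empirical value). The MQ sum over the non-MQ0
reads uses a normal approximation to the sum of truncated-discrete MAPQ
draws (mean 57, sd 3, capped at 60), clipped to its feasible range — the
downstream statistics only consume the sum, so per-read draws would buy
nothing at these depths. Defaults: 10 samples at 8× each, 1 Mb genome
(chr1 400 kb, chr2 300 kb, chrX 200 kb, chrY 100 kb), female fraction
0.51, read length 100, depth multipliers 0.2 (low), 3.0 (high), 0 (N-gap).
The low multiplier must stay below 0.5 and the high above 2.0 so planted
regions are separable from the accessibility windows by construction.

A second route emits actual SAM records (all-match CIGARs, per-sample read
groups, optional duplicate/secondary/supplementary flags at configured
rates) with segment-uniform placement at matching Poisson counts; its exact
recount agrees with the direct route in expectation, with read-length edge
ramps at segment boundaries (adjacent sites are correlated over ~1 read
length, which widens the effective standard error by ~√read_length). All
randomness descends from one seed through named substreams hashed per
(purpose, chromosome, sample), so adding a chromosome or sample leaves
other draws unchanged.

Ground truth is not a hardcoded label list: the expected category of every
planted region *and* of each chromosome's baseline is obtained by running
the classification rules on the noise-free expected site statistics implied
by the config. This keeps the truth self-consistent — with 51% females,
chrY's expected depth (24.5% of the autosomal mean) falls below the 50% low
bound, so its baseline expectation is L, which the built mask then
confirms.

### What the simulator does not model

No realistic read sequences, base-call errors, indels, fragment-level
coverage autocorrelation, GC bias, or ALT-contig placement. Passing
recovery tests therefore shows that the classification machinery recovers
regions whose statistics deviate as configured; it does not validate
behaviour under real-data artefacts such as mapping bias or batch effects.

### Scale artefact of the strict MQ0 rule

The strict Z bound (0.1%) was designed for archive-scale depth, where a
single MQ0 read at a 20,360× site is 0.005% and background MQ0 noise never
trips the rule. At toy depth (~80×) one background MQ0 read is already
1.25%, so the strict mask flags ~8% of perfectly ordinary baseline sites as
Z. This is a property of the rule at low depth, not a defect; recovery
tests against planted ground truth therefore use the pilot profile, while
the strict profile is exercised by the boundary-exact classification tests,
the nesting invariant (every strict-P base is pilot-P), and the threshold
derivation checks.

## Quality binning

The shipped 8-level scheme follows Illumina's published quality-binning
white paper (0–1→0, 2–9→6, 10–19→15, 20–24→22, 25–29→27, 30–34→33,
35–39→37, ≥40→40); it is industry configuration shipped for convenience,
not a product of this package's analyses, and any contiguous scheme can be
substituted from a 3-column text file. Binning is monotone and idempotent
by construction.

## Problem sizes and numerics

Tests run on genomes of 50 kb–1 Mb with cohort depths near 80×, sizes at
which every planted effect is ≥4σ from its classification boundary, so
seeded recovery assertions (≥95% agreement inside planted regions, ≥99%
elsewhere) hold with large margin. Statistical assertions use 3–4 standard
errors of the relevant estimator; classification and pileup assertions are
exact (integer equality against independent oracles: a longhand truth
table over a boundary ±1 grid, and a base-at-a-time naive recount).
Summary fractions are exact ratios of int64 counts; only their TSV
rendering rounds (2 decimal places), so a printed row of six categories
can sum to 100% ± 0.03.

## Known limitations

- SAM text is the native alignment interface; BAM/CRAM work through the
  same pysam reader but are not exercised by the shipped tests.
- Masks for two assemblies can be summarized side by side but not lifted
  between assemblies.
- Overlapping mate pairs are double-counted (no per-fragment
  de-duplication), matching simple depth semantics.
- The coverage histogram keeps the counted depths in memory to answer
  exact quantile queries; at toy scale this is negligible, at full genome
  scale a binned-only variant would be preferable.
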