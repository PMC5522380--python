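"""Synthetic multi-sample pileups with planted ground truth.

The simulator emulates the statistical regime the mask analysis assumes: a
cohort of short-read samples whose summed coverage is roughly uniform on
autosomes, reduced on the sex chromosomes according to the cohort sex mix,
and locally perturbed by planted features — assembly gaps (N runs),
coverage dropouts, coverage pileups, repeat regions shedding
mapping-quality-0 reads, and regions of depressed mapping quality.

Two generation routes share one model.  :func:`simulate_pileup` draws the
per-site statistics directly — total depth is Poisson with rate
``sample_count × per_sample_mean_depth × region multiplier × copy factor``
(a sum of per-sample Poissons is itself Poisson), the MQ0 count is binomial
in the depth, and the MQ sum follows a normal approximation to the sum of
per-read mapping qualities.  :func:`simulate_alignments` emits actual SAM
records (all-match CIGARs, per-sample read groups) whose exact recount
reproduces the same statistics in expectation, for exercising the streaming
accumulator.  The sex-chromosome copy factor is ``1`` for autosomes,
``(1+f)/2`` for chrX and ``(1−f)/2`` for chrY with ``f`` the female
fraction; pseudoautosomal intervals (factor 1) are accepted but default to
none.

All randomness descends from a single seed through named substreams, one
per (purpose, chromosome[, sample]), so adding a chromosome or sample does
not perturb the draws of the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pysam

from .mask import MaskProfile, PILOT, classify_site, derive_thresholds
from .pileup import PileupTrack, SiteStats
from .reference import Reference

__all__ = [
    "REGION_KINDS",
    "PlantedRegion",
    "SimConfig",
    "GroundTruth",
    "make_reference",
    "simulate_pileup",
    "simulate_alignments",
    "write_sam",
    "example_config",
]

REGION_KINDS = ("n_gap", "low_coverage", "high_coverage", "repeat_mq0", "low_mq")

SEX_CHROMOSOME_NAMES = {"chrX": "X", "chrY": "Y", "X": "X", "Y": "Y"}


@dataclass(frozen=True)
class PlantedRegion:
    """A feature planted on one chromosome; 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic cohort; all outputs are pure
    functions of this object (including ``seed``).

    ``depth_multipliers`` scale the local Poisson rate inside planted
    regions; the low-coverage multiplier must stay below 0.5 and the
    high-coverage one above 2.0 so planted regions are separable from the
    accessibility windows by construction.
    """

    chromosomes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 400_000, "chr2": 300_000,
                                 "chrX": 200_000, "chrY": 100_000}
    )
    sample_count: int = 10
    female_fraction: float = 0.51
    per_sample_mean_depth: float = 8.0
    read_length: int = 100
    regions: tuple[PlantedRegion, ...] = ()
    depth_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {
            "n_gap": 0.0,
            "low_coverage": 0.2,
            "high_coverage": 3.0,
            "repeat_mq0": 1.0,
            "low_mq": 1.0,
        }
    )
    mq0_fraction: float = 0.5
    mq0_background: float = 0.001  # free parameter: MQ0 rate outside repeats
    mq_mean: float = 57.0
    mq_sd: float = 3.0
    mq_max: int = 60
    low_mq_mean: float = 40.0
    duplicate_rate: float = 0.0
    secondary_rate: float = 0.0
    supplementary_rate: float = 0.0
    par_regions: Mapping[str, tuple[tuple[int, int], ...]] = field(
        default_factory=dict
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must lie in [0, 1]")
        if self.sample_count < 1:
            raise ValueError("sample_count must be positive")
        mult = dict(self.depth_multipliers)
        if mult.get("low_coverage", 0.2) >= 0.5:
            raise ValueError("low_coverage multiplier must be < 0.5")
        if mult.get("high_coverage", 3.0) <= 2.0:
            raise ValueError("high_coverage multiplier must be > 2.0")
        by_chrom: dict[str, list[PlantedRegion]] = {}
        for r in self.regions:
            if r.chrom not in self.chromosomes:
                raise ValueError(f"planted region on unknown chromosome {r.chrom!r}")
            if r.end > self.chromosomes[r.chrom]:
                raise ValueError(
                    f"region [{r.start}, {r.end}) exceeds {r.chrom} length "
                    f"{self.chromosomes[r.chrom]}"
                )
            by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, rs in by_chrom.items():
            rs = sorted(rs, key=lambda r: r.start)
            for a, b in zip(rs, rs[1:]):
                if a.end > b.start:
                    raise ValueError(
                        f"overlapping planted regions on {chrom}: "
                        f"[{a.start},{a.end}) and [{b.start},{b.end})"
                    )

    # -- derived views -------------------------------------------------

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.chromosomes if c not in SEX_CHROMOSOME_NAMES]

    def copy_factor(self, chrom: str) -> float:
        """Cohort-average chromosome copy number relative to autosomes."""
        sex = SEX_CHROMOSOME_NAMES.get(chrom)
        f = self.female_fraction
        if sex == "X":
            return (2 * f + (1 - f)) / 2
        if sex == "Y":
            return (1 - f) / 2
        return 1.0

    def regions_on(self, chrom: str) -> list[PlantedRegion]:
        return sorted(
            (r for r in self.regions if r.chrom == chrom), key=lambda r: r.start
        )

    def segments_on(self, chrom: str) -> list[tuple[int, int, str | None]]:
        """Partition of the chromosome into (start, end, kind-or-None)."""
        segs: list[tuple[int, int, str | None]] = []
        pos = 0
        for r in self.regions_on(chrom):
            if r.start > pos:
                segs.append((pos, r.start, None))
            segs.append((r.start, r.end, r.kind))
            pos = r.end
        if pos < self.chromosomes[chrom]:
            segs.append((pos, self.chromosomes[chrom], None))
        return segs

    def _region_params(self, kind: str | None) -> tuple[float, float, float]:
        """(depth multiplier, MQ0 probability, mean MQ of non-MQ0 reads)."""
        if kind is None:
            return 1.0, self.mq0_background, self.mq_mean
        mult = dict(self.depth_multipliers)[kind]
        p0 = self.mq0_fraction if kind == "repeat_mq0" else self.mq0_background
        mu = self.low_mq_mean if kind == "low_mq" else self.mq_mean
        return mult, p0, mu

    def rng(self, *names: object) -> np.random.Generator:
        """Named substream of the global seed (stable across config edits)."""
        tag = hashlib.sha256("/".join(map(str, names)).encode()).digest()[:4]
        return np.random.default_rng(
            [self.seed, int.from_bytes(tag, "big") % (2**31)]
        )


def example_config(seed: int = 0) -> SimConfig:
    """The default study conditions: 10 samples at 8× each over a 1 Mb toy
    genome (two autosomes plus chrX/chrY, sex mix 51:49 female:male) with one
    planted region of each kind on the autosomes."""
    return SimConfig(
        seed=seed,
        regions=(
            PlantedRegion("chr1", 50_000, 70_000, "n_gap"),
            PlantedRegion("chr1", 120_000, 140_000, "low_coverage"),
            PlantedRegion("chr1", 200_000, 220_000, "high_coverage"),
            PlantedRegion("chr1", 280_000, 300_000, "repeat_mq0"),
            PlantedRegion("chr2", 100_000, 110_000, "n_gap"),
            PlantedRegion("chr2", 200_000, 215_000, "repeat_mq0"),
        ),
    )


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"), dtype="U1")


def make_reference(config: SimConfig) -> Reference:
    """Random A/C/G/T sequence per chromosome with planted N-gap runs."""
    ref = Reference()
    for chrom, length in config.chromosomes.items():
        rng = config.rng("reference", chrom)
        seq = _BASES[rng.integers(0, 4, size=length)]
        for r in config.regions_on(chrom):
            if r.kind == "n_gap":
                seq[r.start : r.end] = "N"
        ref.sequences[chrom] = "".join(seq.tolist())
    return ref


# ---------------------------------------------------------------------------
# direct pileup-level simulation
# ---------------------------------------------------------------------------


def _expected_autosomal_mean_depth(config: SimConfig) -> float:
    """Closed-form mean of the simulated depth over non-N autosomal sites."""
    num = 0.0
    sites = 0
    base = config.sample_count * config.per_sample_mean_depth
    for chrom in config.autosomes:
        for s, e, kind in config.segments_on(chrom):
            if kind == "n_gap":
                continue
            mult, _, _ = config._region_params(kind)
            num += base * mult * (e - s)
            sites += e - s
    if sites == 0:
        raise ValueError("no non-N autosomal sites in config")
    return num / sites


def _expected_autosomal_mean_mq(config: SimConfig) -> float:
    """Closed-form read-weighted mean MQ over non-N autosomal sites."""
    mq_total = 0.0
    depth_total = 0.0
    base = config.sample_count * config.per_sample_mean_depth
    for chrom in config.autosomes:
        for s, e, kind in config.segments_on(chrom):
            if kind == "n_gap":
                continue
            mult, p0, mu = config._region_params(kind)
            d = base * mult * (e - s)
            depth_total += d
            mq_total += d * (1 - p0) * mu
    return mq_total / depth_total if depth_total else 0.0


@dataclass
class GroundTruth:
    """Expected mask categories implied by the noise-free simulation model.

    ``regions`` lists the planted intervals (0-based half-open) with the
    category each should receive; ``baseline`` gives the expected category
    of the unplanted remainder of each chromosome (P on autosomes, but e.g.
    L on chrY whenever the cohort's expected Y depth falls below the
    autosomal-derived low bound).  ``profile_name`` records the rule set the
    expectations were evaluated under.
    """

    regions: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)
    baseline: dict[str, str] = field(default_factory=dict)
    profile_name: str = "pilot"

    def expected_codes(self, lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
        """Dense per-base expected category arrays."""
        out: dict[str, np.ndarray] = {}
        for chrom, n in lengths.items():
            arr = np.full(n, self.baseline.get(chrom, "P"), dtype="U1")
            for s, e, cat in self.regions.get(chrom, []):
                arr[s:e] = cat
            out[chrom] = arr
        return out

    def planted_mask(self, lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
        """Boolean arrays flagging planted positions."""
        out: dict[str, np.ndarray] = {}
        for chrom, n in lengths.items():
            flag = np.zeros(n, dtype=bool)
            for s, e, _ in self.regions.get(chrom, []):
                flag[s:e] = True
            out[chrom] = flag
        return out

    def write_bed(self, path: "str | Path") -> None:
        with open(path, "w") as fh:
            for chrom, ivals in self.regions.items():
                for s, e, cat in ivals:
                    fh.write(f"{chrom}\t{s}\t{e}\t{cat}\n")


def ground_truth(config: SimConfig, profile: MaskProfile = PILOT) -> GroundTruth:
    """Evaluate the classification rules on the expected site statistics."""
    mean_depth = _expected_autosomal_mean_depth(config)
    cutoff = (
        _expected_autosomal_mean_mq(config)
        if profile.use_avg_mq_criterion
        else None
    )
    thr = derive_thresholds(mean_depth, profile, cutoff)
    base_depth = config.sample_count * config.per_sample_mean_depth

    def expected_cat(chrom: str, kind: str | None) -> str:
        if kind == "n_gap":
            return "N"
        mult, p0, mu = config._region_params(kind)
        d = base_depth * mult * config.copy_factor(chrom)
        stats = SiteStats(d, d * p0, d * (1 - p0) * mu)  # real-valued, same rules
        return classify_site(stats, "A", thr)

    truth = GroundTruth(profile_name=profile.name)
    for chrom in config.chromosomes:
        truth.baseline[chrom] = expected_cat(chrom, None)
        truth.regions[chrom] = [
            (r.start, r.end, expected_cat(chrom, r.kind))
            for r in config.regions_on(chrom)
        ]
    return truth


def simulate_pileup(
    config: SimConfig,
    reference: Reference | None = None,
    profile: MaskProfile = PILOT,
) -> tuple[PileupTrack, GroundTruth]:
    """Draw per-site statistics directly from the cohort model.

    ``reference`` is only consulted for consistency (lengths); pass the
    output of :func:`make_reference` on the same config or None.
    """
    if reference is not None and reference.lengths != dict(config.chromosomes):
        raise ValueError("reference does not match config chromosome lengths")
    track = PileupTrack.zeros(config.chromosomes)
    base = config.sample_count * config.per_sample_mean_depth
    for chrom, length in config.chromosomes.items():
        rng = config.rng("pileup", chrom)
        factor = config.copy_factor(chrom)
        lam = np.full(length, base * factor)
        p0 = np.full(length, config.mq0_background)
        mu = np.full(length, config.mq_mean)
        for par_start, par_end in config.par_regions.get(chrom, ()):
            lam[par_start:par_end] = base  # PAR: diploid in everyone
        for r in config.regions_on(chrom):
            mult, p, m = config._region_params(r.kind)
            lam[r.start : r.end] *= mult
            p0[r.start : r.end] = p
            mu[r.start : r.end] = m
        depth = rng.poisson(lam)
        mq0 = rng.binomial(depth, p0)
        informative = depth - mq0  # reads contributing non-zero MQ
        raw = rng.normal(informative * mu, np.sqrt(np.maximum(informative, 1))
                         * config.mq_sd)
        mq_sum = np.clip(np.rint(raw), 0, informative * config.mq_max)
        mq_sum[informative == 0] = 0
        track.depth[chrom] = depth.astype(np.int64)
        track.mq0[chrom] = mq0.astype(np.int64)
        track.mq_sum[chrom] = mq_sum.astype(np.int64)
    return track, ground_truth(config, profile)


# ---------------------------------------------------------------------------
# read-level simulation
# ---------------------------------------------------------------------------


def _sample_sex_factors(config: SimConfig) -> list[dict[str, float]]:
    """Per-sample copy factors; the first round(f·n) samples are female."""
    n_female = int(round(config.female_fraction * config.sample_count))
    factors = []
    for i in range(config.sample_count):
        female = i < n_female
        factors.append({"X": 1.0 if female else 0.5,
                        "Y": 0.0 if female else 0.5})
    return factors


def sam_header(config: SimConfig) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": c, "LN": int(n)} for c, n in config.chromosomes.items()
            ],
            "RG": [
                {"ID": f"S{i:03d}", "SM": f"sample{i:03d}"}
                for i in range(config.sample_count)
            ],
        }
    )


def simulate_alignments(
    config: SimConfig, reference: Reference
) -> Iterator[pysam.AlignedSegment]:
    """Emit SAM records realizing the cohort model read by read.

    Reads are all-match (CIGAR ``<read_length>M``), placed uniformly within
    each region segment at a Poisson count matching the segment's target
    depth; MAPQ is 0 with the segment's MQ0 probability and otherwise drawn
    from the truncated discrete baseline distribution.  Duplicate /
    secondary / supplementary flags are injected at the configured rates.
    Records come out coordinate-sorted per chromosome.
    """
    rl = config.read_length
    for length in config.chromosomes.values():
        if length < rl:
            raise ValueError("chromosome shorter than read_length")
    header = sam_header(config)
    sex_factors = _sample_sex_factors(config)
    serial = 0
    for chrom, length in config.chromosomes.items():
        sex = SEX_CHROMOSOME_NAMES.get(chrom)
        reads: list[tuple[int, int, int, int]] = []  # (pos, mapq, flag, sample)
        for sample in range(config.sample_count):
            rng = config.rng("alignments", chrom, sample)
            sfac = sex_factors[sample][sex] if sex else 1.0
            if sfac == 0.0:
                continue
            for s, e, kind in config.segments_on(chrom):
                mult, p0, mu = config._region_params(kind)
                target = config.per_sample_mean_depth * mult * sfac
                if target <= 0:
                    continue
                n_reads = rng.poisson(target * (e - s) / rl)
                if n_reads == 0:
                    continue
                pos = rng.integers(s, e, size=n_reads)
                pos = np.minimum(pos, length - rl)
                is0 = rng.random(n_reads) < p0
                mapq = np.rint(
                    np.clip(rng.normal(mu, config.mq_sd, size=n_reads),
                            1, config.mq_max)
                ).astype(int)
                mapq[is0] = 0
                flag = np.zeros(n_reads, dtype=int)
                if config.duplicate_rate:
                    flag |= 0x400 * (rng.random(n_reads) < config.duplicate_rate)
                if config.secondary_rate:
                    flag |= 0x100 * (rng.random(n_reads) < config.secondary_rate)
                if config.supplementary_rate:
                    flag |= 0x800 * (rng.random(n_reads) < config.supplementary_rate)
                reads.extend(
                    zip(pos.tolist(), mapq.tolist(), flag.tolist(),
                        [sample] * n_reads)
                )
        reads.sort(key=lambda r: r[0])
        seq = reference.sequences[chrom]
        for pos, mapq, flag, sample in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = f"r{serial:08d}"
            serial += 1
            a.flag = flag
            a.reference_name = chrom
            a.reference_start = pos
            a.mapping_quality = mapq
            a.cigarstring = f"{rl}M"
            a.query_sequence = seq[pos : pos + rl].replace("N", "A")
            a.query_qualities = pysam.qualitystring_to_array("I" * rl)
            a.set_tag("RG", f"S{sample:03d}")
            yield a


def write_sam(
    records: Iterator[pysam.AlignedSegment],
    config: SimConfig,
    path: "str | Path",
) -> int:
    """Write records as SAM text; returns the record count."""
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=sam_header(config)) as out:
        for rec in records:
            out.write(rec)
            n += 1
    return n
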