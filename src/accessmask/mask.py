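"""Genome accessibility masks: threshold derivation and per-base
classification into the six site categories.

Each reference base receives exactly one code, tested in fixed precedence:

===== ==============================================================
code  meaning
===== ==============================================================
``N`` the reference base itself is N
``L`` accumulated read depth below the low bound
``H`` accumulated read depth above the high bound
``Z`` too large a fraction of spanning reads has mapping quality 0
``Q`` site-average mapping quality below the cutoff (strict only)
``P`` passed: the site is accessible
===== ==============================================================

Two built-in rule sets mirror the 1000 Genomes mask conventions.  The
*pilot* mask allows a 2-fold coverage deviation from the autosomal mean
(bounds ``0.5×`` and ``2.0×`` the mean, inclusive) and tolerates up to 20%
MQ0 reads (inclusive).  The *strict* mask narrows the window to
``0.5×``–``1.5×``, fails any site where the MQ0 fraction reaches 0.1%
(exclusive bound: "fewer than 0.1%"), and additionally requires the
site-average mapping quality to be at or above the autosomal read-weighted
average.  Applied to a cohort with autosomal mean total depth 20,360×,
these rules give the pilot window 10,180×–40,720× and the strict window
10,180×–30,540×.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pileup import PileupTrack, SiteStats
from .reference import Reference

__all__ = [
    "CATEGORIES",
    "MaskProfile",
    "MaskThresholds",
    "MaskTrack",
    "AccessibilitySummary",
    "PILOT",
    "STRICT",
    "autosomal_mean_depth",
    "autosomal_mean_mq",
    "derive_thresholds",
    "classify_site",
    "build_mask",
    "summarize_mask",
    "mask_to_bed",
    "mask_from_intervals",
    "write_bed",
    "write_mask_fasta",
    "read_mask_fasta",
]

CATEGORIES = ("N", "L", "H", "Z", "Q", "P")

_FASTA_WIDTH = 60


@dataclass(frozen=True)
class MaskProfile:
    """A mask rule set expressed relative to the genome-wide mean depth.

    ``mq0_inclusive`` controls the sense of the MQ0 bound: when True a site
    *passes* at exactly ``mq0_fraction_max`` ("20% or fewer"); when False it
    *fails* there ("fewer than 0.1%" admits only strictly smaller fractions).
    """

    name: str
    depth_low_multiplier: float
    depth_high_multiplier: float
    mq0_fraction_max: float
    mq0_inclusive: bool
    use_avg_mq_criterion: bool

    def __post_init__(self) -> None:
        if not 0 < self.depth_low_multiplier < self.depth_high_multiplier:
            raise ValueError(
                "require 0 < depth_low_multiplier < depth_high_multiplier"
            )
        if not 0 <= self.mq0_fraction_max <= 1:
            raise ValueError("mq0_fraction_max must be within [0, 1]")


PILOT = MaskProfile(
    name="pilot",
    depth_low_multiplier=0.5,
    depth_high_multiplier=2.0,
    mq0_fraction_max=0.20,
    mq0_inclusive=True,
    use_avg_mq_criterion=False,
)

STRICT = MaskProfile(
    name="strict",
    depth_low_multiplier=0.5,
    depth_high_multiplier=1.5,
    mq0_fraction_max=0.001,
    mq0_inclusive=False,
    use_avg_mq_criterion=True,
)

BUILTIN_PROFILES: dict[str, MaskProfile] = {"pilot": PILOT, "strict": STRICT}


@dataclass(frozen=True)
class MaskThresholds:
    """A profile resolved against a concrete mean depth: absolute cutoffs.

    Depth bounds are inclusive at both ends; thresholds are kept as exact
    reals (no rounding), so an integer mean reproduces printed bounds
    exactly (mean 20,360 → 10,180 / 40,720 / 30,540).
    """

    depth_low: float
    depth_high: float
    mq0_fraction_max: float
    mq0_inclusive: bool
    avg_mq_min: float | None
    profile_name: str

    def __post_init__(self) -> None:
        if self.depth_low > self.depth_high:
            raise ValueError("depth_low must not exceed depth_high")


def autosomal_mean_depth(
    track: PileupTrack,
    reference: Reference,
    autosome_names: Sequence[str],
) -> float:
    """Mean per-site total depth over non-N positions of the named autosomes.

    This is the genome-wide anchor from which both mask profiles derive
    their absolute depth windows.
    """
    autosome_names = list(autosome_names)
    if not autosome_names:
        raise ValueError("empty autosome set")
    missing = [c for c in autosome_names if c not in track.depth]
    if missing:
        raise ValueError(f"autosomes absent from track: {missing}")
    total = 0
    sites = 0
    for chrom in autosome_names:
        keep = ~reference.n_mask(chrom)
        total += int(track.depth[chrom][keep].sum())
        sites += int(keep.sum())
    if sites == 0:
        raise ValueError("no non-N autosomal sites")
    return total / sites


def autosomal_mean_mq(
    track: PileupTrack,
    reference: Reference,
    autosome_names: Sequence[str],
) -> float:
    """Read-weighted mean mapping quality over non-N autosomal sites,
    ``Σ mq_sum / Σ depth`` — the strict profile's average-MQ cutoff."""
    autosome_names = list(autosome_names)
    if not autosome_names:
        raise ValueError("empty autosome set")
    mq_total = 0
    depth_total = 0
    for chrom in autosome_names:
        keep = ~reference.n_mask(chrom)
        mq_total += int(track.mq_sum[chrom][keep].sum())
        depth_total += int(track.depth[chrom][keep].sum())
    if depth_total == 0:
        raise ValueError("zero total autosomal depth; cannot average MQ")
    return mq_total / depth_total


def derive_thresholds(
    mean_depth: float,
    profile: MaskProfile,
    avg_mq_cutoff: float | None = None,
) -> MaskThresholds:
    """Resolve a profile's mean-relative multipliers to absolute cutoffs."""
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if profile.use_avg_mq_criterion and avg_mq_cutoff is None:
        raise ValueError(
            f"profile {profile.name!r} uses the average-MQ criterion; "
            "compute autosomal_mean_mq first and pass it as avg_mq_cutoff"
        )
    return MaskThresholds(
        depth_low=profile.depth_low_multiplier * mean_depth,
        depth_high=profile.depth_high_multiplier * mean_depth,
        mq0_fraction_max=profile.mq0_fraction_max,
        mq0_inclusive=profile.mq0_inclusive,
        avg_mq_min=avg_mq_cutoff if profile.use_avg_mq_criterion else None,
        profile_name=profile.name,
    )


def classify_site(
    stats: SiteStats, base: str, thresholds: MaskThresholds
) -> str:
    """Category code for one site; first matching rule wins (N>L>H>Z>Q>P).

    Depth bounds pass inclusively at both ends; a depth-0 non-N site is L
    before any fraction is formed, so no 0/0 arises.
    """
    if base in ("N", "n"):
        return "N"
    depth = stats.depth
    if depth < thresholds.depth_low:
        return "L"
    if depth > thresholds.depth_high:
        return "H"
    frac = stats.mq0_count / depth
    if thresholds.mq0_inclusive:
        if frac > thresholds.mq0_fraction_max:
            return "Z"
    else:
        if frac >= thresholds.mq0_fraction_max:
            return "Z"
    if thresholds.avg_mq_min is not None:
        if stats.mq_sum / depth < thresholds.avg_mq_min:
            return "Q"
    return "P"


@dataclass
class MaskTrack:
    """One category code per base per chromosome (dtype ``U1`` arrays)."""

    codes: dict[str, np.ndarray] = field(default_factory=dict)
    profile_name: str | None = None

    @property
    def chromosomes(self) -> list[str]:
        return list(self.codes)

    def lengths(self) -> dict[str, int]:
        return {c: a.size for c, a in self.codes.items()}

    def validate(self) -> None:
        valid = np.array(CATEGORIES, dtype="U1")
        for chrom, arr in self.codes.items():
            if not np.isin(arr, valid).all():
                bad = sorted(set(arr) - set(CATEGORIES))
                raise ValueError(f"invalid category codes on {chrom}: {bad}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MaskTrack):
            return NotImplemented
        return set(self.codes) == set(other.codes) and all(
            np.array_equal(self.codes[c], other.codes[c]) for c in self.codes
        )


def build_mask(
    track: PileupTrack,
    reference: Reference,
    thresholds: MaskThresholds,
    chromosomes: Sequence[str] | None = None,
) -> MaskTrack:
    """Classify every base of the selected chromosomes.

    Vectorized positionwise application of :func:`classify_site`; restrict
    ``chromosomes`` to the primary assembly when decoy/ALT sequences are
    present, since multi-mapping there corrupts the MQ0 statistic.
    """
    chroms = list(chromosomes) if chromosomes is not None else track.chromosomes
    mask = MaskTrack(profile_name=thresholds.profile_name)
    for chrom in chroms:
        if chrom not in track.depth or chrom not in reference.sequences:
            raise ValueError(f"chromosome {chrom!r} missing from track or reference")
        if track.depth[chrom].size != len(reference.sequences[chrom]):
            raise ValueError(
                f"length mismatch on {chrom}: track "
                f"{track.depth[chrom].size} vs reference "
                f"{len(reference.sequences[chrom])}"
            )
        depth = track.depth[chrom]
        mq0 = track.mq0[chrom]
        mq_sum = track.mq_sum[chrom]
        is_n = reference.n_mask(chrom)

        safe_depth = np.where(depth > 0, depth, 1)  # depth 0 is L before fractions
        mq0_frac = mq0 / safe_depth
        mean_mq = mq_sum / safe_depth

        if thresholds.mq0_inclusive:
            z_bad = mq0_frac > thresholds.mq0_fraction_max
        else:
            z_bad = mq0_frac >= thresholds.mq0_fraction_max
        conditions = [
            is_n,
            depth < thresholds.depth_low,
            depth > thresholds.depth_high,
            z_bad,
        ]
        choices = ["N", "L", "H", "Z"]
        if thresholds.avg_mq_min is not None:
            conditions.append(mean_mq < thresholds.avg_mq_min)
            choices.append("Q")
        mask.codes[chrom] = np.select(conditions, choices, default="P").astype("U1")
    return mask


@dataclass
class AccessibilitySummary:
    """Per-category base counts and fractions, genome-wide and per chromosome.

    ``counts``/``fractions`` are DataFrames indexed by scope (``genome`` plus
    one row per chromosome) with the category codes as columns in the fixed
    order N, L, H, Z, Q, P.
    """

    counts: pd.DataFrame
    fractions: pd.DataFrame
    profile_name: str | None

    def to_tsv(self, path: "str | Path") -> None:
        with open(path, "w") as fh:
            fh.write(f"#profile={self.profile_name}\n")
            fh.write("#scope\t" + "\t".join(CATEGORIES) + "\ttotal_bases\n")
            for scope in self.fractions.index:
                pct = "\t".join(
                    f"{100 * self.fractions.loc[scope, c]:.2f}%" for c in CATEGORIES
                )
                fh.write(f"{scope}\t{pct}\t{int(self.counts.loc[scope].sum())}\n")


def summarize_mask(
    mask: MaskTrack, profile: MaskProfile | str | None = None
) -> AccessibilitySummary:
    """Count category occupancy per chromosome and genome-wide.

    Passing ``profile`` asserts provenance: summarizing a mask built under a
    different profile is rejected rather than silently mislabeled.
    """
    if profile is not None:
        wanted = profile.name if isinstance(profile, MaskProfile) else profile
        if mask.profile_name is not None and mask.profile_name != wanted:
            raise ValueError(
                f"mask was built with profile {mask.profile_name!r}, "
                f"summary requested for {wanted!r}"
            )
    rows: dict[str, list[int]] = {}
    for chrom, arr in mask.codes.items():
        rows[chrom] = [int((arr == c).sum()) for c in CATEGORIES]
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=list(CATEGORIES))
    genome = counts.sum(axis=0).to_frame().T
    genome.index = ["genome"]
    counts = pd.concat([genome, counts])
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("empty mask scope")
    fractions = counts.div(totals, axis=0)
    return AccessibilitySummary(counts, fractions, mask.profile_name)


def _runs(values: np.ndarray) -> Iterable[tuple[int, int, str]]:
    """Maximal runs of equal values as (start, end, value), 0-based half-open."""
    n = values.size
    if n == 0:
        return
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    for s, e in zip(starts, ends):
        yield int(s), int(e), str(values[s])


def mask_to_bed(
    mask: MaskTrack, categories: "str | Iterable[str]"
) -> list[tuple[str, int, int]]:
    """Maximal runs of the requested categories as sorted 0-based half-open
    ``(chrom, start, end)`` intervals; adjacent runs are merged."""
    if isinstance(categories, str):
        categories = [categories]
    wanted = set(categories)
    unknown = wanted - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown category codes: {sorted(unknown)}")
    out: list[tuple[str, int, int]] = []
    for chrom, arr in mask.codes.items():
        member = np.isin(arr, list(wanted))
        for s, e, v in _runs(member):
            if v == "True":
                out.append((chrom, s, e))
    return out


def mask_from_intervals(
    intervals: Mapping[str, Iterable[tuple[str, int, int]]],
    lengths: Mapping[str, int],
    profile_name: str | None = None,
) -> MaskTrack:
    """Rebuild a mask from per-category BED-style intervals (inverse of
    exporting every category with :func:`mask_to_bed`)."""
    mask = MaskTrack(profile_name=profile_name)
    for chrom, n in lengths.items():
        mask.codes[chrom] = np.full(n, "", dtype="U1")
    for cat, ivals in intervals.items():
        if cat not in CATEGORIES:
            raise ValueError(f"unknown category code: {cat!r}")
        for chrom, s, e in ivals:
            mask.codes[chrom][s:e] = cat
    for chrom, arr in mask.codes.items():
        if (arr == "").any():
            raise ValueError(f"intervals do not tile chromosome {chrom}")
    return mask


def write_bed(
    intervals: Iterable[tuple[str, int, int]],
    path: "str | Path",
    name: str | None = None,
) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in intervals:
            if name is None:
                fh.write(f"{chrom}\t{s}\t{e}\n")
            else:
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


def write_mask_fasta(mask: MaskTrack, path: "str | Path") -> None:
    """Serialize the mask as FASTA whose residues are the category codes."""
    with open(path, "w") as fh:
        for chrom, arr in mask.codes.items():
            fh.write(f">{chrom}\n")
            seq = "".join(arr.tolist())
            for i in range(0, len(seq), _FASTA_WIDTH):
                fh.write(seq[i : i + _FASTA_WIDTH] + "\n")


def read_mask_fasta(path: "str | Path") -> MaskTrack:
    mask = MaskTrack()
    name: str | None = None
    chunks: list[str] = []
    def flush() -> None:
        if name is not None:
            mask.codes[name] = np.array(list("".join(chunks)), dtype="U1")
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    flush()
    mask.validate()
    return mask
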