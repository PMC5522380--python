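"""Per-site, cross-sample pileup statistics from alignment records.

The unit of information is the :class:`SiteStats` triple — total read depth,
count of mapping-quality-0 (MQ0) reads, and the sum of mapping qualities —
aggregated over every sample at every reference position.  These three
numbers are all the downstream accessibility-mask classification needs:
depth bounds, the MQ0 fraction ``mq0_count/depth`` and the site-average
mapping quality ``mq_sum/depth``.

Records are streamed once; per-chromosome dense integer arrays hold the
accumulating statistics, so memory is proportional to genome length and
independent of read count.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple

import numpy as np
import pysam

__all__ = [
    "SiteStats",
    "PileupTrack",
    "ReadFilter",
    "InputFormatError",
    "accumulate_site_stats",
    "merge_tracks",
    "write_stats_table",
    "read_stats_table",
]

# CIGAR operation codes that consume reference bases.
_CIG_M, _CIG_D, _CIG_N, _CIG_EQ, _CIG_X = 0, 2, 3, 7, 8
_ALIGNED_OPS = {_CIG_M, _CIG_EQ, _CIG_X}


class InputFormatError(ValueError):
    """Malformed input data (SAM record, stats table row, scheme file...)."""


class SiteStats(NamedTuple):
    """Aggregate read statistics at one reference position."""

    depth: int
    mq0_count: int
    mq_sum: int

    @property
    def mq0_fraction(self) -> float:
        return self.mq0_count / self.depth if self.depth else 0.0

    @property
    def mean_mq(self) -> float:
        return self.mq_sum / self.depth if self.depth else float("nan")


@dataclass
class PileupTrack:
    """Dense per-chromosome arrays of site statistics.

    Arrays are indexed 0-based internally; position ``p`` (1-based, SAM
    convention) lives at index ``p - 1``.
    """

    depth: dict[str, np.ndarray] = field(default_factory=dict)
    mq0: dict[str, np.ndarray] = field(default_factory=dict)
    mq_sum: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def zeros(cls, lengths: Mapping[str, int]) -> "PileupTrack":
        t = cls()
        for name, n in lengths.items():
            t.depth[name] = np.zeros(int(n), dtype=np.int64)
            t.mq0[name] = np.zeros(int(n), dtype=np.int64)
            t.mq_sum[name] = np.zeros(int(n), dtype=np.int64)
        return t

    @property
    def chromosomes(self) -> list[str]:
        return list(self.depth)

    def lengths(self) -> dict[str, int]:
        return {c: a.size for c, a in self.depth.items()}

    def site(self, chrom: str, position: int) -> SiteStats:
        """Stats at 1-based ``position`` on ``chrom``."""
        i = position - 1
        return SiteStats(
            int(self.depth[chrom][i]),
            int(self.mq0[chrom][i]),
            int(self.mq_sum[chrom][i]),
        )

    def validate(self) -> None:
        for c in self.depth:
            d, z, s = self.depth[c], self.mq0[c], self.mq_sum[c]
            if not (d.size == z.size == s.size):
                raise ValueError(f"ragged arrays on {c}")
            if (z > d).any() or (z < 0).any() or (s < 0).any():
                raise ValueError(f"SiteStats invariant violated on {c}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PileupTrack):
            return NotImplemented
        if set(self.depth) != set(other.depth):
            return False
        return all(
            np.array_equal(self.depth[c], other.depth[c])
            and np.array_equal(self.mq0[c], other.mq0[c])
            and np.array_equal(self.mq_sum[c], other.mq_sum[c])
            for c in self.depth
        )


@dataclass(frozen=True)
class ReadFilter:
    """Which alignment records count toward the pileup.

    Defaults give conventional depth semantics: unmapped, secondary,
    supplementary, duplicate-flagged and QC-fail records are dropped, every
    MAPQ (including 0) is kept — the MQ0-fraction criterion needs the MQ0
    reads in the denominator — and deletion-spanning (CIGAR ``D``) reference
    positions count as covered.  Duplicate handling is a switch because
    archive-style pipelines mark duplicates without removing them.
    """

    exclude_unmapped: bool = True
    exclude_secondary: bool = True
    exclude_supplementary: bool = True
    exclude_duplicates: bool = True
    exclude_qcfail: bool = True
    min_mapq: int = 0
    count_deletions: bool = True

    def keep(self, read: pysam.AlignedSegment) -> bool:
        if self.exclude_unmapped and read.is_unmapped:
            return False
        if self.exclude_secondary and read.is_secondary:
            return False
        if self.exclude_supplementary and read.is_supplementary:
            return False
        if self.exclude_duplicates and read.is_duplicate:
            return False
        if self.exclude_qcfail and read.is_qcfail:
            return False
        if read.mapping_quality < self.min_mapq:
            return False
        return True


def _iter_records(
    records: "str | Path | pysam.AlignmentFile | Iterable[pysam.AlignedSegment]",
) -> Iterator[pysam.AlignedSegment]:
    if isinstance(records, (str, Path)):
        with pysam.AlignmentFile(str(records), "r", check_sq=False) as fh:
            yield from fh
    else:
        yield from records


def reference_spans(
    read: pysam.AlignedSegment, count_deletions: bool = True
) -> list[tuple[int, int]]:
    """0-based half-open reference intervals covered by ``read``.

    M/=/X operations always cover; D covers when ``count_deletions``;
    N (reference skip) never covers.  Adjacent covered operations are merged.
    """
    if read.cigartuples is None:
        raise InputFormatError(f"record {read.query_name!r} has no CIGAR")
    spans: list[tuple[int, int]] = []
    pos = read.reference_start
    for op, length in read.cigartuples:
        if op in _ALIGNED_OPS or (op == _CIG_D and count_deletions):
            if spans and spans[-1][1] == pos:
                spans[-1] = (spans[-1][0], pos + length)
            else:
                spans.append((pos, pos + length))
            pos += length
        elif op in (_CIG_D, _CIG_N):
            pos += length
    return spans


def accumulate_site_stats(
    records: "str | Path | pysam.AlignmentFile | Iterable[pysam.AlignedSegment]",
    reference_index: Mapping[str, int],
    read_filter: ReadFilter | None = None,
) -> PileupTrack:
    """Stream alignment records into a :class:`PileupTrack`.

    Parameters
    ----------
    records
        Path to a SAM file (BAM/CRAM work through the same pysam reader), an
        open :class:`pysam.AlignmentFile`, or an iterable of records.
    reference_index
        Chromosome name → length.  A record placed on a chromosome absent
        from this mapping is an error naming the chromosome.
    read_filter
        Record-retention policy; defaults to :class:`ReadFilter` defaults.
    """
    flt = read_filter if read_filter is not None else ReadFilter()
    track = PileupTrack.zeros(reference_index)
    for read in _iter_records(records):
        if read.is_unmapped and read.reference_name is None:
            if flt.exclude_unmapped:
                continue
            # placed nowhere: contributes to no site either way
            continue
        if not flt.keep(read):
            continue
        chrom = read.reference_name
        if chrom not in reference_index:
            raise InputFormatError(
                f"record {read.query_name!r} references unknown chromosome {chrom!r}"
            )
        length = reference_index[chrom]
        mapq = read.mapping_quality
        d, z, s = track.depth[chrom], track.mq0[chrom], track.mq_sum[chrom]
        for start, end in reference_spans(read, flt.count_deletions):
            start, end = max(start, 0), min(end, length)
            if start >= end:
                continue
            d[start:end] += 1
            s[start:end] += mapq
            if mapq == 0:
                z[start:end] += 1
    return track


def merge_tracks(tracks: Iterable[PileupTrack]) -> PileupTrack:
    """Element-wise sum of tracks (e.g. per-sample accumulations)."""
    tracks = list(tracks)
    if not tracks:
        raise ValueError("no tracks to merge")
    lengths = tracks[0].lengths()
    for t in tracks[1:]:
        if t.lengths() != lengths:
            raise ValueError(
                f"cannot merge tracks with differing chromosomes: "
                f"{lengths} vs {t.lengths()}"
            )
    out = PileupTrack.zeros(lengths)
    for t in tracks:
        for c in lengths:
            out.depth[c] += t.depth[c]
            out.mq0[c] += t.mq0[c]
            out.mq_sum[c] += t.mq_sum[c]
    return out


_STATS_HEADER = "#chrom\tpos\tdepth\tmq0_count\tmq_sum"


def write_stats_table(track: PileupTrack, path: "str | Path") -> None:
    """Write the per-site TSV (1-based positions; all-zero sites omitted)."""
    with open(path, "w") as fh:
        fh.write(_STATS_HEADER + "\n")
        for chrom in track.chromosomes:
            d, z, s = track.depth[chrom], track.mq0[chrom], track.mq_sum[chrom]
            nz = np.flatnonzero((d != 0) | (z != 0) | (s != 0))
            for i in nz:
                fh.write(f"{chrom}\t{i + 1}\t{d[i]}\t{z[i]}\t{s[i]}\n")


def read_stats_table(
    path: "str | Path", reference_index: Mapping[str, int]
) -> PileupTrack:
    """Read the per-site TSV back into a dense track (omitted sites = zeros)."""
    track = PileupTrack.zeros(reference_index)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise InputFormatError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                pos, depth, mq0, mq_sum = (int(x) for x in fields[1:])
            except ValueError as exc:
                raise InputFormatError(f"{path}:{lineno}: non-integer field") from exc
            if chrom not in reference_index:
                raise InputFormatError(
                    f"{path}:{lineno}: unknown chromosome {chrom!r}"
                )
            if not 1 <= pos <= reference_index[chrom]:
                raise InputFormatError(
                    f"{path}:{lineno}: position {pos} outside {chrom} "
                    f"(length {reference_index[chrom]})"
                )
            if mq0 > depth or mq0 < 0 or depth < 0 or mq_sum < 0:
                raise InputFormatError(
                    f"{path}:{lineno}: invalid site statistics"
                )
            i = pos - 1
            track.depth[chrom][i] = depth
            track.mq0[chrom][i] = mq0
            track.mq_sum[chrom][i] = mq_sum
    return track
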