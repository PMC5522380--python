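"""Lossy base-quality binning of the kind applied before CRAM conversion.

Archive pipelines shrink alignment files by collapsing the ~40-level Phred
quality range onto a handful of representative values before reference-based
compression.  A :class:`BinningScheme` is an ordered list of contiguous
inclusive score ranges, each mapped to one representative inside the range;
binning is therefore monotone and idempotent, and never increases the number
of distinct quality values in a stream.

The shipped default, :data:`ILLUMINA_8BIN`, follows Illumina's published
8-level quality binning white paper (it is industry configuration, not a
product of this package's analyses): qualities 2–9 → 6, 10–19 → 15,
20–24 → 22, 25–29 → 27, 30–34 → 33, 35–39 → 37 and ≥40 → 40, with the
no-call scores 0–1 kept at 0.  Any valid scheme can be substituted from a
3-column text file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam

from .pileup import InputFormatError

__all__ = ["BinningScheme", "ILLUMINA_8BIN", "bin_quality", "bin_stream",
           "read_scheme", "write_scheme"]


@dataclass(frozen=True)
class BinningScheme:
    """Ordered (low, high, representative) triples, inclusive ranges.

    Ranges must be contiguous, non-overlapping, start at 0, and each
    representative must lie within its range.
    """

    bins: tuple[tuple[int, int, int], ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValueError("scheme needs at least one bin")
        expect_low = 0
        for low, high, rep in self.bins:
            if low != expect_low:
                raise ValueError(
                    f"bins must be contiguous from 0: got low={low}, "
                    f"expected {expect_low}"
                )
            if high < low:
                raise ValueError(f"empty range {low}..{high}")
            if not low <= rep <= high:
                raise ValueError(
                    f"representative {rep} outside its range {low}..{high}"
                )
            expect_low = high + 1

    @property
    def max_score(self) -> int:
        return self.bins[-1][1]

    def lookup(self) -> np.ndarray:
        """Dense score → representative table of length max_score + 1."""
        table = np.empty(self.max_score + 1, dtype=np.uint8)
        for low, high, rep in self.bins:
            table[low : high + 1] = rep
        return table


ILLUMINA_8BIN = BinningScheme(
    bins=(
        (0, 1, 0),
        (2, 9, 6),
        (10, 19, 15),
        (20, 24, 22),
        (25, 29, 27),
        (30, 34, 33),
        (35, 39, 37),
        (40, 93, 40),
    ),
    name="illumina-8bin",
)


def bin_quality(q: int, scheme: BinningScheme = ILLUMINA_8BIN) -> int:
    """Representative score of the bin containing ``q``."""
    if not 0 <= q <= scheme.max_score:
        raise ValueError(
            f"quality {q} outside scheme coverage 0..{scheme.max_score}"
        )
    for low, high, rep in scheme.bins:
        if low <= q <= high:
            return rep
    raise AssertionError("unreachable: scheme ranges are contiguous")


def bin_stream(
    records: Iterable[pysam.AlignedSegment],
    scheme: BinningScheme = ILLUMINA_8BIN,
) -> Iterator[pysam.AlignedSegment]:
    """Transform per-base qualities of a record stream; order preserved."""
    table = scheme.lookup()
    for rec in records:
        quals = rec.query_qualities
        if quals is not None:
            arr = np.asarray(quals, dtype=np.int64)
            if arr.size and (arr.max() > scheme.max_score or arr.min() < 0):
                raise ValueError(
                    f"record {rec.query_name!r} has quality outside "
                    f"scheme coverage 0..{scheme.max_score}"
                )
            rec.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in table[arr])
            )
        yield rec


def read_scheme(path: "str | Path", name: str | None = None) -> BinningScheme:
    """Read a 3-column (low, high, representative) scheme file."""
    bins: list[tuple[int, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 3:
                raise InputFormatError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            try:
                bins.append(tuple(int(x) for x in fields))  # type: ignore[arg-type]
            except ValueError as exc:
                raise InputFormatError(
                    f"{path}:{lineno}: non-integer field"
                ) from exc
    try:
        return BinningScheme(tuple(bins), name=name or Path(path).stem)
    except ValueError as exc:
        raise InputFormatError(f"{path}: {exc}") from exc


def write_scheme(scheme: BinningScheme, path: "str | Path") -> None:
    with open(path, "w") as fh:
        fh.write(f"# quality binning scheme: {scheme.name}\n# low high representative\n")
        for low, high, rep in scheme.bins:
            fh.write(f"{low}\t{high}\t{rep}\n")
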