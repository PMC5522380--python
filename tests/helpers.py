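"""Shared test utilities: SAM record construction and independent oracles.

The oracles here deliberately avoid the library's code paths: the
classification oracle is a longhand truth table and the pileup oracle is a
naive per-position counter, so agreement with the implementation is a real
cross-check, not a tautology.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping

import numpy as np
import pysam


def make_header(lengths: Mapping[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": c, "LN": int(n)} for c, n in lengths.items()],
        }
    )


def make_read(
    header: pysam.AlignmentHeader,
    chrom: str,
    start: int,
    length: int = 100,
    mapq: int = 60,
    flag: int = 0,
    cigar: str | None = None,
    name: str = "read",
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.flag = flag
    a.reference_name = chrom
    a.reference_start = start
    a.mapping_quality = mapq
    a.cigarstring = cigar or f"{length}M"
    qlen = a.infer_query_length() or length
    a.query_sequence = "A" * qlen
    a.query_qualities = pysam.qualitystring_to_array("I" * qlen)
    return a


# ---------------------------------------------------------------------------
# classification oracle: longhand truth table
# ---------------------------------------------------------------------------


def classify_oracle(
    depth: float,
    mq0: float,
    mq_sum: float,
    base: str,
    mean_depth: float,
    profile: str,
    avg_mq_cutoff: float | None = None,
) -> str:
    """Expected category, written out rule by rule per profile.

    pilot: depth within [0.5·mean, 2·mean] inclusive, MQ0 fraction 20% or
    fewer.  strict: depth within [0.5·mean, 1.5·mean] inclusive, MQ0
    fraction strictly below 0.1%, site-average MQ at or above the cutoff.
    """
    if base.upper() == "N":
        return "N"
    if profile == "pilot":
        if depth < 0.5 * mean_depth:
            return "L"
        if depth > 2.0 * mean_depth:
            return "H"
        if mq0 / depth > 0.20:
            return "Z"
        return "P"
    if profile == "strict":
        if depth < 0.5 * mean_depth:
            return "L"
        if depth > 1.5 * mean_depth:
            return "H"
        if mq0 / depth >= 0.001:
            return "Z"
        if mq_sum / depth < avg_mq_cutoff:
            return "Q"
        return "P"
    raise ValueError(profile)


# ---------------------------------------------------------------------------
# pileup oracle: naive per-position recount
# ---------------------------------------------------------------------------


def naive_recount(
    reads: Iterable[pysam.AlignedSegment],
    lengths: Mapping[str, int],
    exclude_duplicates: bool = True,
    exclude_secondary: bool = True,
    exclude_supplementary: bool = True,
    exclude_qcfail: bool = True,
    min_mapq: int = 0,
    count_deletions: bool = True,
) -> dict[str, dict[str, Counter]]:
    """Depth/MQ0/MQ-sum per position by incrementing one base at a time."""
    out = {
        c: {"depth": Counter(), "mq0": Counter(), "mq_sum": Counter()}
        for c in lengths
    }
    for read in reads:
        if read.is_unmapped:
            continue
        if exclude_duplicates and read.is_duplicate:
            continue
        if exclude_secondary and read.is_secondary:
            continue
        if exclude_supplementary and read.is_supplementary:
            continue
        if exclude_qcfail and read.is_qcfail:
            continue
        if read.mapping_quality < min_mapq:
            continue
        ctr = out[read.reference_name]
        pos = read.reference_start
        for op, ln in read.cigartuples:
            if op in (0, 7, 8) or (op == 2 and count_deletions):
                for p in range(pos, pos + ln):
                    if 0 <= p < lengths[read.reference_name]:
                        ctr["depth"][p] += 1
                        ctr["mq_sum"][p] += read.mapping_quality
                        if read.mapping_quality == 0:
                            ctr["mq0"][p] += 1
                pos += ln
            elif op in (2, 3):
                pos += ln
    return out


def counters_to_arrays(
    counters: dict[str, dict[str, Counter]], lengths: Mapping[str, int]
) -> dict[str, dict[str, np.ndarray]]:
    out: dict[str, dict[str, np.ndarray]] = {}
    for chrom, n in lengths.items():
        out[chrom] = {}
        for key in ("depth", "mq0", "mq_sum"):
            arr = np.zeros(n, dtype=np.int64)
            for p, v in counters[chrom][key].items():
                arr[p] = v
            out[chrom][key] = arr
    return out
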