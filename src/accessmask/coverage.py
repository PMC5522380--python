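"""Per-chromosome coverage/mapping-quality summaries, coverage histograms,
and the expected sex-chromosome depth model.

For a cohort with female fraction *f*, the expected total depth on the
non-pseudoautosomal portion of the sex chromosomes, relative to the
autosomal mean *m*, follows from chromosome copy numbers: females carry two
X and no Y, males one of each, so

    E[X depth] = m · (2f + (1 − f)) / 2        E[Y depth] = m · (1 − f) / 2

— approximately three-quarters and one-quarter of the autosomal depth for a
balanced cohort.  Observed chrY depth typically exceeds this expectation
because palindromic repeats attract multi-mapping (MQ0) reads, which is why
median coverage and the per-chromosome MQ0 totals are reported alongside
the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pileup import PileupTrack
from .reference import Reference

__all__ = [
    "ChromosomeSummary",
    "CoverageHistogram",
    "chromosome_summary",
    "coverage_histogram",
    "expected_sex_chromosome_depth",
    "write_summary_tsv",
]


@dataclass(frozen=True)
class ChromosomeSummary:
    """One chromosome's aggregate statistics across all samples.

    ``mean_mq`` is read-weighted (Σ mq_sum / Σ depth) and NaN — not 0 —
    when the chromosome has no aligned reads.
    """

    chromosome: str
    mean_mq: float
    mq0_total: int
    mean_depth: float
    site_count: int


def chromosome_summary(
    track: PileupTrack,
    reference: Reference | None = None,
    include_n_sites: bool = False,
) -> list[ChromosomeSummary]:
    """Mean MQ, total MQ0 read count and mean depth per chromosome.

    N sites are excluded from the site count (and hence the depth mean) by
    default; they carry no alignment signal.  Without a reference every
    site counts.
    """
    out = []
    for chrom in track.chromosomes:
        depth = track.depth[chrom]
        mq0 = track.mq0[chrom]
        mq_sum = track.mq_sum[chrom]
        if reference is not None and not include_n_sites:
            keep = ~reference.n_mask(chrom)
            depth, mq0, mq_sum = depth[keep], mq0[keep], mq_sum[keep]
        d_tot = int(depth.sum())
        out.append(
            ChromosomeSummary(
                chromosome=chrom,
                mean_mq=(int(mq_sum.sum()) / d_tot) if d_tot else float("nan"),
                mq0_total=int(mq0.sum()),
                mean_depth=(d_tot / depth.size) if depth.size else float("nan"),
                site_count=int(depth.size),
            )
        )
    return out


def write_summary_tsv(
    summaries: Sequence[ChromosomeSummary], path: "str | Path"
) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tmean_mq\tmq0_total\tmean_depth\tsites\n")
        for s in summaries:
            mq = "NA" if math.isnan(s.mean_mq) else f"{s.mean_mq:.4f}"
            fh.write(
                f"{s.chromosome}\t{mq}\t{s.mq0_total}\t"
                f"{s.mean_depth:.4f}\t{s.site_count}\n"
            )


@dataclass
class CoverageHistogram:
    """Depth distribution of one chromosome's (non-N) sites.

    Bins are ``[k·w, (k+1)·w)`` from zero; ``fractions`` are of the counted
    sites.  ``median_depth`` is carried because on repeat-heavy chromosomes
    (chrY) the mean is inflated by multi-mapping pileups while the median
    stays near the copy-number expectation.
    """

    chromosome: str
    bin_width: float
    edges: np.ndarray
    counts: np.ndarray
    fractions: np.ndarray
    median_depth: float
    depths: np.ndarray  # the counted per-site depths, for exact quantile queries

    def fraction_at_or_above(self, level: float) -> float:
        """Fraction of counted sites with depth ≥ level."""
        if self.depths.size == 0:
            return float("nan")
        return float((self.depths >= level).mean())

    def fraction_between(self, low: float, high: float) -> float:
        """Fraction of counted sites with low ≤ depth < high."""
        if self.depths.size == 0:
            return float("nan")
        return float(((self.depths >= low) & (self.depths < high)).mean())

    def to_tsv(self, path: "str | Path") -> None:
        with open(path, "w") as fh:
            fh.write(f"#chromosome={self.chromosome}\tbin_width={self.bin_width}"
                     f"\tmedian_depth={self.median_depth}\n")
            fh.write("#bin_low\tbin_high\tsites\tfraction\n")
            for i, c in enumerate(self.counts):
                fh.write(
                    f"{self.edges[i]:g}\t{self.edges[i + 1]:g}\t{int(c)}\t"
                    f"{self.fractions[i]:.6f}\n"
                )


def coverage_histogram(
    track: PileupTrack,
    chromosome: str,
    bin_width: float,
    reference: Reference | None = None,
    include_n_sites: bool = False,
) -> CoverageHistogram:
    """Histogram of per-site total depth on one chromosome."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if chromosome not in track.depth:
        raise ValueError(f"unknown chromosome {chromosome!r}")
    depth = track.depth[chromosome]
    if reference is not None and not include_n_sites:
        depth = depth[~reference.n_mask(chromosome)]
    if depth.size == 0:
        raise ValueError(f"no sites to histogram on {chromosome}")
    n_bins = int(depth.max() // bin_width) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(depth, bins=edges)
    return CoverageHistogram(
        chromosome=chromosome,
        bin_width=float(bin_width),
        edges=edges,
        counts=counts,
        fractions=counts / depth.size,
        median_depth=float(np.median(depth)),
        depths=depth,
    )


def expected_sex_chromosome_depth(
    autosomal_mean: float, female_fraction: float
) -> tuple[float, float]:
    """Expected non-PAR total depth on (chrX, chrY) given the cohort sex mix.

    Linear in ``autosomal_mean``; X increases and Y decreases with the
    female fraction.  At ``female_fraction=0.5`` the pair is exactly
    (¾·mean, ¼·mean).
    """
    if not 0 <= female_fraction <= 1:
        raise ValueError("female_fraction must lie in [0, 1]")
    if autosomal_mean < 0:
        raise ValueError("autosomal_mean must be non-negative")
    f = female_fraction
    x = autosomal_mean * (2 * f + (1 - f)) / 2
    y = autosomal_mean * (1 - f) / 2
    return x, y
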