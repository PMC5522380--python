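"""Minimal reference-genome container shared by the simulator and the mask
builder: ordered chromosome sequences, N-run lookup, FASTA round trip."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pyfaidx import Fasta

__all__ = ["Reference"]

_FASTA_WIDTH = 60


@dataclass
class Reference:
    """Chromosome name → sequence (uppercase A/C/G/T/N)."""

    sequences: dict[str, str] = field(default_factory=dict)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    @property
    def chromosomes(self) -> list[str]:
        return list(self.sequences)

    def n_mask(self, chrom: str) -> np.ndarray:
        """Boolean array, True where the base is 'N' (case-insensitive)."""
        arr = np.frombuffer(self.sequences[chrom].encode("ascii"), dtype="S1")
        return (arr == b"N") | (arr == b"n")

    def write_fasta(self, path: "str | Path") -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), _FASTA_WIDTH):
                    fh.write(seq[i : i + _FASTA_WIDTH] + "\n")

    @classmethod
    def from_fasta(cls, path: "str | Path") -> "Reference":
        with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
            return cls({name: str(rec[:]) for name, rec in fa.items()})
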