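"""Shared low-level helpers: sequence alphabet, reverse complement, genomic intervals."""
from __future__ import annotations

from dataclasses import dataclass

DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAATGCAA")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (returned in DNA alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str) -> bool:
    return not set(seq.upper()) - set("ACGTUN")


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open internally.

    GFF3 serialization (1-based inclusive) lives in :mod:`mirprof.io`; the
    conversion happens only at the file boundary.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"
    category: str = ""
    source: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start
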