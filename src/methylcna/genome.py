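"""Genome coordinate bookkeeping.

All coordinates inside the package are 0-based, half-open intervals
``[start, end)``; conversions to 1-based inclusive SEG happen only at I/O
boundaries (see :mod:`methylcna.io`).
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GenomeModel:
    """An ordered set of chromosomes with lengths in base pairs.

    ``total_size`` is the denominator of percent genome altered (PGA):
    the cumulative length of gained/lost segments is divided by the whole
    genome size.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(self.chrom_names) == 0:
            raise ValueError("genome must contain at least one chromosome")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if any(length <= 0 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def total_size(self) -> int:
        return int(sum(self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names

    @classmethod
    def toy(cls, n_chroms: int = 5, chrom_size: int = 50_000_000) -> "GenomeModel":
        """Desk-scale genome: ``n_chroms`` chromosomes of ``chrom_size`` bp.

        The 5 x 50 Mb default is large enough to exercise multi-chromosome
        bookkeeping while keeping simulated cohorts fast to generate.
        """
        return cls(
            chrom_names=tuple(f"chr{i + 1}" for i in range(n_chroms)),
            chrom_lengths=tuple(chrom_size for _ in range(n_chroms)),
        )
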