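"""Genome annotation containers.

All coordinates are 0-based half-open (BED convention). Conversion to/from
1-based dialects happens only in :mod:`ervchip.io` readers/writers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence


@dataclass(frozen=True)
class RepeatRecord:
    """One RepeatMasker-style repeat copy."""

    chrom: str
    start: int
    end: int
    strand: str
    rep_name: str
    rep_class: str
    rep_family: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"degenerate repeat {self.rep_name} at {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class GeneRecord:
    """Minimal gene model: TSS/TES anchors plus an exon interval list.

    ``tss``/``tes`` are single-base positions; for a minus-strand gene the
    TSS is the rightmost transcribed base. Exons are half-open intervals.
    """

    chrom: str
    tss: int
    tes: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()
    name: str = ""

    @property
    def body(self) -> tuple[int, int]:
        lo, hi = sorted((self.tss, self.tes))
        return lo, hi + 1


@dataclass
class GenomeModel:
    """Chromosome sizes plus repeat and gene annotation for a genome."""

    chrom_sizes: dict[str, int]
    repeats: list[RepeatRecord] = field(default_factory=list)
    genes: list[GeneRecord] = field(default_factory=list)
    sex_chrom_names: frozenset[str] = frozenset({"chrX", "chrY"})

    def __post_init__(self) -> None:
        for name, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {size}")
        for rep in self.repeats:
            self._check_interval(rep.chrom, rep.start, rep.end, f"repeat {rep.rep_name}")
        for gene in self.genes:
            lo, hi = gene.body
            self._check_interval(gene.chrom, lo, hi, f"gene {gene.name or gene.tss}")

    def _check_interval(self, chrom: str, start: int, end: int, what: str) -> None:
        if chrom not in self.chrom_sizes:
            raise ValueError(f"{what}: unknown chromosome {chrom!r}")
        if start < 0 or end > self.chrom_sizes[chrom]:
            raise ValueError(
                f"{what}: interval [{start}, {end}) outside {chrom} "
                f"(length {self.chrom_sizes[chrom]})"
            )

    @property
    def autosome_names(self) -> list[str]:
        return [c for c in self.chrom_sizes if c not in self.sex_chrom_names]

    def total_length(self, chroms: Sequence[str] | None = None) -> int:
        names = chroms if chroms is not None else list(self.chrom_sizes)
        return sum(self.chrom_sizes[c] for c in names)

    def n_start_sites(self, read_length: int, chroms: Sequence[str] | None = None) -> int:
        """Distinct (position, strand) start sites for reads of ``read_length``."""
        names = chroms if chroms is not None else list(self.chrom_sizes)
        return sum(
            2 * max(self.chrom_sizes[c] - read_length + 1, 0) for c in names
        )
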