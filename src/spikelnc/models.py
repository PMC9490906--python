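"""Core domain types shared across the pipeline.

All positions are 0-based half-open internally; GTF and VCF coordinates are
converted on read/write, BED passes through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: The nine Triticum/Aegilops population groups, ordered along the
#: diploid -> tetraploid -> hexaploid series used throughout the analysis.
GROUP_LABELS = ("A1", "A2", "A3", "AB1", "AB2", "AB3", "ABD1", "ABD2", "D1")

#: Accession counts per group in the re-sequencing panel (sum = 261).
GROUP_SIZES = {
    "A1": 31,
    "A2": 31,
    "A3": 29,
    "AB1": 28,
    "AB2": 29,
    "AB3": 13,
    "ABD1": 45,
    "ABD2": 25,
    "D1": 30,
}

MISSING = -1  # genotype / allele missing code
TRANS_DISTANCE = float("inf")  # sentinel for cross-chromosome feature pairs


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def span(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def gap_to(self, other: "GenomicInterval") -> float:
        """Nearest-edge gap in bp; 0 when overlapping, inf across chromosomes."""
        if self.chrom != other.chrom:
            return TRANS_DISTANCE
        if self.start < other.end and other.start < self.end:
            return 0.0
        return float(max(self.start, other.start) - min(self.end, other.end))


@dataclass
class TranscriptModel:
    """An exon-structured transcript model.

    Exons are sorted, pairwise disjoint, share the transcript's chromosome
    and strand, and lie within ``interval``.
    """

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]
    biotype: str = "unknown"  # mRNA | lncRNA-candidate | unknown

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for e in self.exons:
            if e.chrom != self.interval.chrom or e.strand != self.interval.strand:
                raise ValueError(
                    f"{self.transcript_id}: exon chrom/strand mismatch"
                )
            if not self.interval.contains(e):
                raise ValueError(f"{self.transcript_id}: exon outside interval")
            if prev_end is not None and e.start < prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = e.end

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def length(self) -> int:
        """Spliced transcript length (sum of exon lengths)."""
        return sum(e.span for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Ordered (start, end) intron coordinates between consecutive exons."""
        return [
            (self.exons[i].end, self.exons[i + 1].start)
            for i in range(len(self.exons) - 1)
        ]


@dataclass(frozen=True)
class Site:
    """One bi-allelic SNP site."""

    interval: GenomicInterval  # length-1
    ref: str
    alt: str


@dataclass
class VariantPanel:
    """Bi-allelic genotype matrix with a population-group map.

    genotypes holds allele-dosage codes {0, 1, 2}, MISSING (-1) for no-calls.
    haplotypes holds per-chromosome-copy alleles (sites x samples x 2) where
    phase is known (phased het, or any homozygote); MISSING elsewhere.
    """

    sites: list[Site]
    samples: list[str]
    genotypes: np.ndarray  # (n_sites, n_samples) int8 dosage
    sample_groups: dict[str, str]
    haplotypes: Optional[np.ndarray] = None  # (n_sites, n_samples, 2) int8
    skipped_records: int = 0
    sample_index: dict = field(init=False, repr=False)

    def __post_init__(self):
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError("genotype matrix shape mismatch")
        bad = set(np.unique(self.genotypes)) - {-1, 0, 1, 2}
        if bad:
            raise ValueError(f"invalid genotype codes {sorted(bad)}")
        missing_groups = [s for s in self.samples if s not in self.sample_groups]
        if missing_groups:
            raise ValueError(
                f"samples without a group assignment: {missing_groups}"
            )
        order = sorted(
            range(len(self.sites)),
            key=lambda i: (self.sites[i].interval.chrom, self.sites[i].interval.start),
        )
        if order != list(range(len(self.sites))):
            self.sites = [self.sites[i] for i in order]
            self.genotypes = self.genotypes[order]
            if self.haplotypes is not None:
                self.haplotypes = self.haplotypes[order]
        self.sample_index = {s: i for i, s in enumerate(self.samples)}

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def group_members(self, group: str) -> list[int]:
        """Column indices of the samples belonging to ``group``."""
        return [
            i for i, s in enumerate(self.samples) if self.sample_groups[s] == group
        ]

    def sites_in(self, interval: GenomicInterval) -> np.ndarray:
        """Row indices of sites within a half-open interval."""
        return np.array(
            [
                i
                for i, s in enumerate(self.sites)
                if s.interval.chrom == interval.chrom
                and interval.start <= s.interval.start < interval.end
            ],
            dtype=int,
        )
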