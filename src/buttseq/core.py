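"""Core coordinate types and the single-nucleotide signal container.

Every coordinate inside the package is 0-based, half-open ``[start, end)``.
SAM and GTF records (1-based, inclusive) are converted at the I/O boundary and
nowhere else, so all downstream arithmetic shares a single convention.

The central analyte is :class:`SingleNtSignal`, a sparse per-(chrom, strand)
map of genomic position -> count of nascent-RNA 3' ends, i.e. the last base
synthesized by an RNA polymerase molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np

STRANDS = ("+", "-", ".")
GENE_STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand/name/score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def strand_matches(self, strand: str) -> bool:
        return self.strand == "." or strand == "." or self.strand == strand


@dataclass
class GeneModel:
    """A gene with strand, exon structure and derived TSS/TES.

    Exons are stored in genomic order (sorted by start), non-overlapping.
    The TSS is the first transcribed base: ``start`` of the gene footprint on
    '+', ``end - 1`` on '-'.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in GENE_STRANDS:
            raise ValueError(f"gene strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            if a.chrom != b.chrom:
                raise ValueError(f"gene {self.gene_id}: exons on multiple chroms")

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    def offset_to_genomic(self, offset: int) -> int:
        """Map a transcription-order offset from the TSS to a genomic position."""
        return self.tss + offset if self.strand == "+" else self.tss - offset

    def genomic_to_offset(self, pos: int) -> int:
        return pos - self.tss if self.strand == "+" else self.tss - pos

    def is_exonic(self, pos: int) -> bool:
        return any(e.contains(pos) for e in self.exons)

    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class AnnotationSet:
    """Gene models plus the contaminant interval classes used for masking/QC."""

    genes: list[GeneModel]
    small_rna: list[GenomicInterval] = field(default_factory=list)
    exon_three_prime_ends: list[GenomicInterval] = field(default_factory=list)
    rrna: list[GenomicInterval] = field(default_factory=list)
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.chrom_sizes:
            known = set(self.chrom_sizes)
            for g in self.genes:
                if g.chrom not in known:
                    raise ValueError(f"gene {g.gene_id} on unknown chrom {g.chrom}")
            for group in (self.small_rna, self.exon_three_prime_ends, self.rrna):
                for iv in group:
                    if iv.chrom not in known:
                        raise ValueError(f"interval on unknown chrom {iv.chrom}")

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class AlignedPair:
    """A properly paired alignment with UMI and read-2 soft-clip bookkeeping.

    ``r2_strand`` is the mapping strand of read 2; the strand of the nascent
    RNA is derived from it in :mod:`buttseq.preprocess` according to the
    configured library orientation. Soft-clip lengths are in sequencing order:
    ``r2_leading_softclip`` is adjacent to the first sequenced base of read 2.
    """

    chrom: str
    r1_start: int
    r1_end: int
    r2_start: int
    r2_end: int
    r2_strand: str
    umi: str
    name: str = ""
    r2_leading_softclip: int = 0
    r2_trailing_softclip: int = 0
    softclips_stripped: bool = False

    def __post_init__(self) -> None:
        if self.r2_strand not in GENE_STRANDS:
            raise ValueError(f"read-2 strand must be '+' or '-', got {self.r2_strand!r}")
        if not (self.r1_start < self.r1_end and self.r2_start < self.r2_end):
            raise ValueError(f"pair {self.name}: empty mate span")

    @property
    def r1_strand(self) -> str:
        # proper FR pair: mates map to opposite strands
        return "-" if self.r2_strand == "+" else "+"

    @property
    def r2_five_prime(self) -> int:
        """First aligned base of read 2 in sequencing order."""
        return self.r2_start if self.r2_strand == "+" else self.r2_end - 1

    @property
    def r1_five_prime(self) -> int:
        return self.r1_start if self.r1_strand == "+" else self.r1_end - 1


class SingleNtSignal:
    """Sparse stranded per-base counts of polymerase 3'-end positions.

    Counts are integers for raw signal and may be floats after normalization.
    """

    def __init__(self) -> None:
        self._counts: dict[tuple[str, str], dict[int, float]] = {}
        self._cache: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}

    # -- construction ------------------------------------------------------
    @classmethod
    def from_dict(cls, data: Mapping[tuple[str, str], Mapping[int, float]]) -> "SingleNtSignal":
        sig = cls()
        for key, posmap in data.items():
            for pos, c in posmap.items():
                sig.add(key[0], key[1], pos, c)
        return sig

    def add(self, chrom: str, strand: str, pos: int, count: float = 1) -> None:
        if strand not in GENE_STRANDS:
            raise ValueError(f"signal strand must be '+' or '-', got {strand!r}")
        if count == 0:
            return
        key = (chrom, strand)
        d = self._counts.setdefault(key, {})
        d[pos] = d.get(pos, 0) + count
        if d[pos] == 0:
            del d[pos]
        self._cache.pop(key, None)

    # -- queries -----------------------------------------------------------
    def get(self, chrom: str, strand: str, pos: int) -> float:
        return self._counts.get((chrom, strand), {}).get(pos, 0)

    def keys(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(self._counts))

    def items(self) -> Iterator[tuple[tuple[str, str], dict[int, float]]]:
        for key in sorted(self._counts):
            yield key, self._counts[key]

    def positions(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted position and count arrays for one (chrom, strand)."""
        key = (chrom, strand)
        if key not in self._cache:
            d = self._counts.get(key, {})
            pos = np.array(sorted(d), dtype=np.int64)
            cnt = np.array([d[p] for p in pos], dtype=float)
            self._cache[key] = (pos, cnt)
        return self._cache[key]

    def total(self) -> float:
        return float(sum(sum(d.values()) for d in self._counts.values()))

    def n_positions(self) -> int:
        return sum(len(d) for d in self._counts.values())

    def window_sum(self, chrom: str, strand: str, start: int, end: int) -> float:
        """Total signal over ``[start, end)`` on one strand."""
        if end <= start:
            return 0.0
        pos, cnt = self.positions(chrom, strand)
        if len(pos) == 0:
            return 0.0
        lo, hi = np.searchsorted(pos, (start, end))
        return float(cnt[lo:hi].sum())

    def array(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """Dense per-base counts over ``[start, end)``."""
        out = np.zeros(end - start, dtype=float)
        pos, cnt = self.positions(chrom, strand)
        if len(pos) == 0:
            return out
        lo, hi = np.searchsorted(pos, (start, end))
        out[pos[lo:hi] - start] = cnt[lo:hi]
        return out

    # -- transforms --------------------------------------------------------
    def scale(self, factor: float) -> "SingleNtSignal":
        """Divide every count by ``factor`` (size-factor normalization)."""
        if factor <= 0:
            raise ValueError("scaling factor must be > 0")
        out = SingleNtSignal()
        for key, d in self._counts.items():
            out._counts[key] = {p: c / factor for p, c in d.items()}
        return out

    def copy(self) -> "SingleNtSignal":
        out = SingleNtSignal()
        for key, d in self._counts.items():
            out._counts[key] = dict(d)
        return out

    def as_dict(self) -> dict[tuple[str, str], dict[int, float]]:
        return {k: dict(v) for k, v in self._counts.items() if v}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SingleNtSignal):
            return NotImplemented
        return self.as_dict() == other.as_dict()

    def __repr__(self) -> str:
        return (
            f"SingleNtSignal({self.n_positions()} positions, "
            f"total={self.total():g})"
        )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent same-strand intervals (per chrom+strand)."""
    by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in intervals:
        by_key.setdefault((iv.chrom, iv.strand), []).append(iv)
    merged: list[GenomicInterval] = []
    for (chrom, strand), ivs in sorted(by_key.items()):
        ivs.sort(key=lambda i: i.start)
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end, strand))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end, strand))
    return merged
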