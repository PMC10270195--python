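"""Aligned pairs -> deduplicated, contaminant-masked, stranded 3'-end signal.

The single-nucleotide conversion truncates each pair to the first base
sequenced by read 2, which is the last nascent-RNA base synthesized by the
polymerase. In this library design read 2 starts at the RNA 3' end and reads
inward, so it maps antisense to the nascent RNA; the reported strand is
therefore the opposite of the read-2 mapping strand by default
(``rna_strand_from_read2="opposite"``), with ``"same"`` available for
libraries with the other orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

from intervaltree import IntervalTree

from .core import (
    AlignedPair,
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    SingleNtSignal,
    merge_intervals,
)

logger = logging.getLogger(__name__)

RNA_STRAND_CONVENTIONS = ("opposite", "same")


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


# ---------------------------------------------------------------------------
# soft clips
# ---------------------------------------------------------------------------

def strip_softclips(pair: AlignedPair) -> AlignedPair:
    """Zero the recorded read-2 soft clips and mark the pair handled.

    Soft-clipped bases have no reference coordinate, so the aligned span is
    unchanged: the 3'-end anchor is the aligned end adjacent to the leading
    (5'-in-sequencing-order) clip, which is exactly ``r2_five_prime``.
    A fully clipped read cannot occur in an aligned record (M length >= 1).
    """
    if pair.softclips_stripped:
        return pair
    return replace(
        pair, r2_leading_softclip=0, r2_trailing_softclip=0, softclips_stripped=True
    )


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

@dataclass
class DedupStats:
    kept: int = 0
    removed: int = 0


def dedup_key(pair: AlignedPair) -> tuple:
    """Exact dedup key: chrom, read-2 strand, both mate 5' positions, UMI."""
    return (pair.chrom, pair.r2_strand, pair.r1_five_prime, pair.r2_five_prime, pair.umi)


def deduplicate(
    pairs: Iterable[AlignedPair], stats: DedupStats | None = None
) -> list[AlignedPair]:
    """Keep exactly one representative (first encountered) per dedup key.

    Exact string match on the UMI; no mismatch-tolerant network collapsing.
    """
    seen: set[tuple] = set()
    kept: list[AlignedPair] = []
    removed = 0
    for pair in pairs:
        key = dedup_key(pair)
        if key in seen:
            removed += 1
            continue
        seen.add(key)
        kept.append(pair)
    if stats is not None:
        stats.kept, stats.removed = len(kept), removed
    logger.info("deduplicate: kept %d, removed %d", len(kept), removed)
    return kept


# ---------------------------------------------------------------------------
# single-nucleotide conversion
# ---------------------------------------------------------------------------

def to_single_nucleotide(
    pair: AlignedPair, rna_strand_from_read2: str = "opposite"
) -> tuple[str, str, int]:
    """(chrom, nascent-RNA strand, polymerase 3'-end position) for one pair.

    Position is the first aligned base of read 2 in sequencing order:
    ``r2_start`` when read 2 maps '+', ``r2_end - 1`` when it maps '-'.
    """
    if rna_strand_from_read2 not in RNA_STRAND_CONVENTIONS:
        raise ValueError(f"unknown strand convention {rna_strand_from_read2!r}")
    strand = (
        _flip(pair.r2_strand) if rna_strand_from_read2 == "opposite" else pair.r2_strand
    )
    return pair.chrom, strand, pair.r2_five_prime


def build_signal(
    pairs: Iterable[AlignedPair], rna_strand_from_read2: str = "opposite"
) -> SingleNtSignal:
    """Accumulate single-nucleotide 3'-end counts over a stream of pairs."""
    sig = SingleNtSignal()
    for pair in pairs:
        chrom, strand, pos = to_single_nucleotide(pair, rna_strand_from_read2)
        sig.add(chrom, strand, pos)
    return sig


# ---------------------------------------------------------------------------
# contaminant masking / report
# ---------------------------------------------------------------------------

def _build_trees(
    intervals: Iterable[GenomicInterval],
) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for iv in intervals:
        strands = ("+", "-") if iv.strand == "." else (iv.strand,)
        for s in strands:
            trees.setdefault((iv.chrom, s), IntervalTree()).addi(iv.start, iv.end)
    return trees


def mask_contaminants(
    signal: SingleNtSignal, ann: AnnotationSet, include_rrna: bool = False
) -> SingleNtSignal:
    """Delete signal positions overlapping small-RNA or exon-3'-end intervals
    (strand-matched); returns a new signal and logs the removed total."""
    mask = list(ann.small_rna) + list(ann.exon_three_prime_ends)
    if include_rrna:
        mask += list(ann.rrna)
    trees = _build_trees(mask)
    out = SingleNtSignal()
    removed = 0.0
    for (chrom, strand), posmap in signal.items():
        tree = trees.get((chrom, strand))
        for pos, c in posmap.items():
            if tree is not None and tree.overlaps_point(pos):
                removed += c
            else:
                out.add(chrom, strand, pos, c)
    logger.info("mask_contaminants: removed %g of %g signal", removed, signal.total())
    return out


def contamination_report(signal: SingleNtSignal, ann: AnnotationSet) -> dict[str, float]:
    """Fractions of total (pre-mask) signal overlapping each contaminant class."""
    total = signal.total()
    fractions: dict[str, float] = {}
    for label, intervals in (("small_rna_fraction", ann.small_rna),
                             ("rrna_fraction", ann.rrna)):
        trees = _build_trees(intervals)
        hit = 0.0
        for (chrom, strand), posmap in signal.items():
            tree = trees.get((chrom, strand))
            if tree is None:
                continue
            for pos, c in posmap.items():
                if tree.overlaps_point(pos):
                    hit += c
        fractions[label] = hit / total if total > 0 else 0.0
    return fractions


# ---------------------------------------------------------------------------
# TSS windows
# ---------------------------------------------------------------------------

@dataclass
class TssWindow:
    """A merged strand-aware TSS-proximal region attributed to its genes."""

    region: GenomicInterval
    gene_ids: list[str] = field(default_factory=list)


def tss_window_interval(gene: GeneModel, window: int = 200) -> GenomicInterval:
    """Strand-aware window covering the first ``window`` transcribed bases."""
    if gene.strand == "+":
        return GenomicInterval(gene.chrom, gene.tss, gene.tss + window, "+", gene.gene_id)
    return GenomicInterval(
        gene.chrom, max(0, gene.tss - window + 1), gene.tss + 1, "-", gene.gene_id
    )


def restrict_to_tss_windows(
    signal: SingleNtSignal, genes: Iterable[GeneModel], window: int = 200
) -> list[tuple[TssWindow, SingleNtSignal]]:
    """Slice signal to the first ``window`` nt downstream of each TSS,
    merging overlapping same-strand windows into one region attributed to all
    member genes."""
    genes = list(genes)
    windows = [tss_window_interval(g, window) for g in genes]
    merged = merge_intervals(windows)
    out: list[tuple[TssWindow, SingleNtSignal]] = []
    for region in merged:
        members = [
            g.gene_id
            for g, w in zip(genes, windows)
            if w.chrom == region.chrom and w.strand == region.strand
            and w.start < region.end and region.start < w.end
        ]
        slice_sig = SingleNtSignal()
        pos, cnt = signal.positions(region.chrom, region.strand)
        for p, c in zip(pos.tolist(), cnt.tolist()):
            if region.start <= p < region.end:
                slice_sig.add(region.chrom, region.strand, p, c)
        out.append((TssWindow(region=region, gene_ids=members), slice_sig))
    return out
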