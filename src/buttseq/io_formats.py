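"""Readers/writers for the standard genomics text formats the pipeline touches.

Strict coordinate conventions: BED and bedGraph are already 0-based half-open
and pass through unchanged; GTF (1-based, inclusive) and SAM are converted to
the internal 0-based half-open convention here and only here. SAM records are
read and written through pysam; FASTA through Biopython.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO

from .core import AlignedPair, GeneModel, GenomicInterval, SingleNtSignal

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, expected_columns: int = 3) -> list[GenomicInterval]:
    """Read a BED file into :class:`GenomicInterval` records.

    Strand defaults to '.' when column 6 is absent. Malformed lines raise
    :class:`ParseError` naming the offending line number.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < max(3, expected_columns):
                raise ParseError(
                    f"{path}:{lineno}: expected >= {max(3, expected_columns)} "
                    f"columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else ""
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
                strand = fields[5] if len(fields) > 5 else "."
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand, name, score))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
            score = 0 if iv.score is None else iv.score
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}"
                f"\t{score:g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _gtf_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in raw.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " in part:
            key, val = part.split(" ", 1)
            attrs[key] = val.strip().strip('"')
    return attrs


def read_gtf_genes(path: str | Path) -> list[GeneModel]:
    """Parse gene models (exon features grouped by ``gene_id``) from a GTF.

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    Genes without exon features are skipped with a warning.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    strands: dict[str, str] = {}
    chroms: dict[str, str] = {}
    seen_genes: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, feature, start1, end1, _score, strand, _frame, attr = fields[:9]
            attrs = _gtf_attributes(attr)
            gid = attrs.get("gene_id")
            if gid is None:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            if gid not in strands:
                seen_genes.append(gid)
                strands[gid] = strand
                chroms[gid] = chrom
            if feature != "exon":
                continue
            start, end = int(start1) - 1, int(end1)  # GTF -> half-open
            exons.setdefault(gid, []).append(GenomicInterval(chrom, start, end, strand))
    genes: list[GeneModel] = []
    for gid in seen_genes:
        if gid not in exons:
            warnings.warn(f"gene {gid} has no exons; skipped")
            continue
        genes.append(GeneModel(gid, chroms[gid], strands[gid], exons[gid]))
    return genes


def write_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as gene + exon GTF features (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            attr = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tbuttseq\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attr}\n"
            )
            for e in g.exons:
                fh.write(
                    f"{g.chrom}\tbuttseq\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{g.strand}\t.\t{attr}\n"
                )


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def _umi_from_name(name: str) -> str:
    if "_" not in name:
        raise ParseError(f"read {name!r}: no UMI suffix after '_' in name")
    return name.rsplit("_", 1)[1]


def _r2_softclips(rec: pysam.AlignedSegment) -> tuple[int, int]:
    """Soft-clip lengths of read 2 in sequencing order (leading, trailing)."""
    cig = rec.cigartuples or []
    first = cig[0][1] if cig and cig[0][0] == 4 else 0
    last = cig[-1][1] if cig and cig[-1][0] == 4 else 0
    # CIGAR is in reference orientation; for a reverse-mapped read the
    # sequencing-order leading clip is the reference-right (last) clip.
    return (last, first) if rec.is_reverse else (first, last)


def read_sam_pairs(path: str | Path) -> Iterator[AlignedPair]:
    """Stream properly paired alignments from a SAM text file as AlignedPair.

    The UMI is parsed from the read-name suffix after the last underscore
    (umi_tools extract convention). Non-proper pairs are dropped with a
    warning; an orphan mate remaining at EOF is also dropped with a warning.
    """
    pending: dict[str, pysam.AlignedSegment] = {}
    n_dropped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or not rec.is_paired or not rec.is_proper_pair:
                n_dropped += 1
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
                continue
            r1, r2 = (rec, mate) if rec.is_read1 else (mate, rec)
            lead, trail = _r2_softclips(r2)
            yield AlignedPair(
                chrom=r1.reference_name,
                r1_start=r1.reference_start,
                r1_end=r1.reference_end,
                r2_start=r2.reference_start,
                r2_end=r2.reference_end,
                r2_strand="-" if r2.is_reverse else "+",
                umi=_umi_from_name(rec.query_name),
                name=rec.query_name,
                r2_leading_softclip=lead,
                r2_trailing_softclip=trail,
            )
    if n_dropped:
        logger.warning("read_sam_pairs: dropped %d non-proper records", n_dropped)
    if pending:
        logger.warning("read_sam_pairs: %d orphan mates at EOF dropped", len(pending))


def write_sam(
    pairs: Iterable[AlignedPair], chrom_sizes: dict[str, int], path: str | Path
) -> None:
    """Write AlignedPairs as proper SAM pairs (text dialect, via pysam)."""
    refs = sorted(chrom_sizes)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": chrom_sizes[c]} for c in refs],
    }
    tid = {c: i for i, c in enumerate(refs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for p in pairs:
            r1 = pysam.AlignedSegment()
            r1.query_name = p.name
            r1.reference_id = tid[p.chrom]
            r1.reference_start = p.r1_start
            r1.cigarstring = f"{p.r1_end - p.r1_start}M"
            r1.flag = (
                0x1 | 0x2 | 0x40
                | (0x10 if p.r1_strand == "-" else 0)
                | (0x20 if p.r2_strand == "-" else 0)
            )
            r1.next_reference_id = tid[p.chrom]
            r1.next_reference_start = p.r2_start
            r1.mapping_quality = 60

            r2 = pysam.AlignedSegment()
            r2.query_name = p.name
            r2.reference_id = tid[p.chrom]
            r2.reference_start = p.r2_start
            m = p.r2_end - p.r2_start
            lead, trail = p.r2_leading_softclip, p.r2_trailing_softclip
            if p.r2_strand == "-":
                # reference orientation: sequencing-order leading clip at right
                cigar = (f"{trail}S" if trail else "") + f"{m}M" + (f"{lead}S" if lead else "")
            else:
                cigar = (f"{lead}S" if lead else "") + f"{m}M" + (f"{trail}S" if trail else "")
            r2.cigarstring = cigar
            r2.flag = (
                0x1 | 0x2 | 0x80
                | (0x10 if p.r2_strand == "-" else 0)
                | (0x20 if p.r1_strand == "-" else 0)
            )
            r2.next_reference_id = tid[p.chrom]
            r2.next_reference_start = p.r1_start
            r2.mapping_quality = 60
            out.write(r1)
            out.write(r2)


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(signal: SingleNtSignal, strand: str, path: str | Path) -> None:
    """Write one strand of a signal as a bedGraph (run-length encoded).

    One line per maximal run of equal nonzero value, sorted by chrom then
    start; the strand is carried by the filename, matching common stranded
    bedGraph practice.
    """
    with open(path, "w") as fh:
        for (chrom, s), _ in signal.items():
            if s != strand:
                continue
            pos, cnt = signal.positions(chrom, strand)
            run_start = run_end = None
            run_val = None
            for p, c in zip(pos.tolist(), cnt.tolist()):
                if run_start is not None and p == run_end and c == run_val:
                    run_end += 1
                    continue
                if run_start is not None:
                    fh.write(f"{chrom}\t{run_start}\t{run_end}\t{run_val:g}\n")
                run_start, run_end, run_val = p, p + 1, c
            if run_start is not None:
                fh.write(f"{chrom}\t{run_start}\t{run_end}\t{run_val:g}\n")


def read_bedgraph(path: str | Path, strand: str) -> SingleNtSignal:
    """Read a bedGraph back into per-base signal on the given strand."""
    sig = SingleNtSignal()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, val = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            for p in range(start, end):
                sig.add(chrom, strand, p, val)
    return sig


# ---------------------------------------------------------------------------
# FASTA / chrom.sizes
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA into {name: uppercase sequence}; duplicate headers error."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ParseError(f"duplicate FASTA header {rec.id!r}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")
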