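"""Ground-truthed synthetic data with the statistical structure of nascent
3'-end sequencing.

The generator emulates the features the downstream analyses assume:

* per-gene single-nucleotide 3'-end signal with one sharp pause site 20-120 bp
  downstream of the TSS plus uniform elongation signal over the gene body;
* 8-bp UMIs with exact-copy PCR duplication (1 + Poisson extra copies);
* small-RNA and rRNA contaminant reads (small RNAs default to ~40% of
  molecules, matching the contamination level typical of 3'-end libraries
  without an exonuclease depletion step);
* subnucleosomal 58 +/- 5 bp MNase fragments with a bimodal dyad-half
  structure at +/-29 bp around each nucleosome center;
* six-time-point sinusoidal transcription (peak ZT14, trough ZT2 by default)
  with an optional constitutive-pause flag per gene;
* two-tissue pause/body signal combinations with planted concordance classes.

All randomness flows from integer seeds through numpy Generators, so output
is bit-reproducible across runs.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import (
    AlignedPair,
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    SingleNtSignal,
)

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _child_seed(seed: int, *tags: int) -> np.random.Generator:
    ss = np.random.SeedSequence([int(seed)] + [int(t) for t in tags])
    return np.random.Generator(np.random.PCG64(ss))


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Fractions are of all sequenced molecules; ``pause_fraction`` is the
    probability that a gene molecule's 3' end sits exactly at the gene's pause
    site rather than uniformly over the body.
    """

    n_genes: int = 200
    gene_length_range: tuple[int, int] = (2000, 5000)
    pause_offset_range: tuple[int, int] = (20, 120)
    pause_fraction: float = 0.3
    body_rate: float = 0.05  # expected reads/bp used for per-gene weighting
    umi_length: int = 8
    pcr_duplication_rate: float = 1.0
    contaminant_fraction: float = 0.4
    rrna_fraction: float = 0.05
    intergenic_gap: int = 2000
    exons_per_gene: tuple[int, int] = (1, 3)
    fragment_length_range: tuple[int, int] = (100, 300)
    read_length_range: tuple[int, int] = (40, 80)
    softclip_prob: float = 0.2
    plant_pause_motif: bool = True
    expression_sigma: float = 0.5
    # circadian mode
    cycling_fraction: float = 0.4
    circadian_amplitude: float = 0.9
    circadian_phase: float = 14.0  # ZT hours
    constitutive_pause_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pause_fraction", "contaminant_fraction", "rrna_fraction",
                     "softclip_prob", "cycling_fraction", "constitutive_pause_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.contaminant_fraction + self.rrna_fraction >= 1.0:
            raise ValueError("contaminant fractions must sum to < 1")
        for name in ("gene_length_range", "pause_offset_range",
                     "fragment_length_range", "read_length_range", "exons_per_gene"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name} must be a nonempty (min, max) range")
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")
        if self.pcr_duplication_rate < 0:
            raise ValueError("pcr_duplication_rate must be >= 0")


@dataclass
class GeneTruth:
    """Per-gene ground truth used by recovery tests."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    length: int
    pause_offset: int
    pause_position: int
    pause_weight: float = 1.0
    expression_weight: float = 1.0
    nucleosome_center: int = 0
    cycling: bool = False
    constitutive_pause: bool = False
    amplitude: float = 0.0
    phase: float = 14.0
    # two-tissue multipliers, set by plant_concordance_classes
    pause_mult: tuple[float, float] = (1.0, 1.0)
    body_mult: tuple[float, float] = (1.0, 1.0)
    pause_class: str = "same"
    body_class: str = "same"


@dataclass
class SimTruth:
    """Simulation ground truth standing in for deposited sequencing data."""

    config: SimConfig
    genes: dict[str, GeneTruth] = field(default_factory=dict)

    def with_pause_shift(self, shift_bp: int, weight_factor: float = 1.0) -> "SimTruth":
        """A perturbed condition: pause offsets moved by ``shift_bp``
        (negative = upstream, toward the TSS) and pause weights scaled."""
        out = SimTruth(config=self.config)
        for gid, gt in self.genes.items():
            new_off = gt.pause_offset + shift_bp
            if new_off < 1:
                raise ValueError(f"{gid}: shifted pause offset {new_off} < 1")
            g2 = GeneTruth(**{**asdict(gt)})
            g2.pause_offset = new_off
            g2.pause_position = (
                gt.tss + new_off if gt.strand == "+" else gt.tss - new_off
            )
            g2.pause_weight = gt.pause_weight * weight_factor
            out.genes[gid] = g2
        return out

    def to_json(self, path: str | Path) -> None:
        data = {
            "config": asdict(self.config),
            "genes": {gid: asdict(gt) for gid, gt in self.genes.items()},
        }
        Path(path).write_text(json.dumps(data, indent=1, default=list))


@dataclass
class ReadSetTruth:
    """Ground truth for one simulated read set.

    ``unique_counts`` counts *distinct deduplication keys*
    (chrom, read-2 strand, mate 5' positions, UMI) per nascent-RNA 3'-end
    position, i.e. exactly what a correct exact-key deduplicator retains.
    """

    n_molecules: int
    n_unique: int
    n_pairs: int
    unique_counts: dict[tuple[str, str, int], int] = field(default_factory=dict)
    pause_reads_per_gene: dict[str, int] = field(default_factory=dict)
    reads_per_gene: dict[str, int] = field(default_factory=dict)
    n_contaminant: int = 0
    n_rrna: int = 0


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> tuple[AnnotationSet, dict[str, str], SimTruth]:
    """Place non-overlapping genes with >= ``intergenic_gap`` bp spacing on
    synthetic chromosomes, assign exon structure and a true pause site per
    gene, drop small-RNA loci into intergenic space, and emit a random genome
    sequence (with the pausing G/T dinucleotide planted around each pause site
    unless disabled)."""
    cfg = config
    rng = _child_seed(cfg.seed, 1)
    margin = 3000
    genes: list[GeneModel] = []
    truth = SimTruth(config=cfg)
    small_rna: list[GenomicInterval] = []
    exon3p: list[GenomicInterval] = []

    # split genes across two chromosomes
    n_chroms = 2 if cfg.n_genes > 1 else 1
    per_chrom = [cfg.n_genes - cfg.n_genes // 2, cfg.n_genes // 2][:n_chroms]
    chrom_sizes: dict[str, int] = {}
    gaps: list[tuple[str, int, int]] = []
    gi = 0
    for ci, n_here in enumerate(per_chrom):
        chrom = f"chrS{ci + 1}"
        cursor = margin
        for _ in range(n_here):
            length = int(rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            start = cursor
            end = start + length
            gid = f"g{gi:04d}"
            exons = _make_exons(rng, chrom, strand, start, end, cfg)
            gene = GeneModel(gid, chrom, strand, exons)
            genes.append(gene)
            off = int(rng.integers(cfg.pause_offset_range[0], cfg.pause_offset_range[1] + 1))
            pause_pos = gene.offset_to_genomic(off)
            truth.genes[gid] = GeneTruth(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                tss=gene.tss,
                tes=gene.tes,
                length=length,
                pause_offset=off,
                pause_position=pause_pos,
                pause_weight=1.0,
                expression_weight=float(rng.lognormal(0.0, cfg.expression_sigma)),
                nucleosome_center=gene.tss,
                cycling=bool(rng.random() < cfg.cycling_fraction),
                amplitude=cfg.circadian_amplitude,
                phase=cfg.circadian_phase,
            )
            gt = truth.genes[gid]
            gt.constitutive_pause = gt.cycling and rng.random() < cfg.constitutive_pause_fraction
            for e in exons:  # last 3 transcribed nt of every exon
                if strand == "+":
                    exon3p.append(GenomicInterval(chrom, max(e.start, e.end - 3), e.end, strand))
                else:
                    exon3p.append(GenomicInterval(chrom, e.start, min(e.end, e.start + 3), strand))
            gap = cfg.intergenic_gap + int(rng.integers(0, 1000))
            gaps.append((chrom, end, end + gap))
            cursor = end + gap
            gi += 1
        chrom_sizes[chrom] = cursor + margin

    # small-RNA loci in intergenic gaps
    n_small = max(3, cfg.n_genes // 10)
    usable = [g for g in gaps if g[2] - g[1] > 600]
    for k in range(n_small):
        if not usable:
            break
        chrom, lo, hi = usable[int(rng.integers(0, len(usable)))]
        length = int(rng.integers(80, 151))
        start = int(rng.integers(lo + 200, hi - 200 - length))
        strand = "+" if rng.random() < 0.5 else "-"
        small_rna.append(GenomicInterval(chrom, start, start + length, strand, f"sno{k:03d}"))

    # rRNA loci get a chromosome of their own (they are intergenic in dm6-like
    # assemblies too; a dedicated contig keeps the bookkeeping simple)
    rrna: list[GenomicInterval] = []
    cursor = margin
    for k in range(3):
        length = int(rng.integers(1000, 3001))
        rrna.append(GenomicInterval("chrRr", cursor, cursor + length, "+", f"rRNA{k}"))
        cursor += length + 2000
    chrom_sizes["chrRr"] = cursor + margin

    genome = {
        chrom: "".join(rng.choice(_BASES, size=size))
        for chrom, size in sorted(chrom_sizes.items())
    }
    if cfg.plant_pause_motif:
        genome = {c: list(s) for c, s in genome.items()}
        for gt in truth.genes.values():
            seq = genome[gt.chrom]
            if gt.strand == "+":
                seq[gt.pause_position - 1] = "G"
                seq[gt.pause_position + 1] = "T"
            else:
                seq[gt.pause_position + 1] = "C"  # complement of G upstream
                seq[gt.pause_position - 1] = "A"  # complement of T downstream
        genome = {c: "".join(s) for c, s in genome.items()}

    ann = AnnotationSet(
        genes=genes,
        small_rna=small_rna,
        exon_three_prime_ends=exon3p,
        rrna=rrna,
        chrom_sizes=chrom_sizes,
    )
    return ann, genome, truth


def _make_exons(rng, chrom, strand, start, end, cfg) -> list[GenomicInterval]:
    """Exon/intron structure in genomic coordinates; the first transcribed
    exon is kept >= 400 bp so pause sites (offset <= ~200) stay exonic."""
    length = end - start
    n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    if n_ex <= 1 or length < 1200:
        return [GenomicInterval(chrom, start, end, strand)]
    # transcription-order offsets: first exon >= 400, introns 200-500, exons >= 200
    bounds = [0]
    pos = int(rng.integers(400, max(401, length // 2)))
    bounds.append(pos)
    for _ in range(n_ex - 1):
        intron = int(rng.integers(200, 501))
        exon = int(rng.integers(200, 801))
        if pos + intron + exon >= length - 200:
            break
        bounds.append(pos + intron)
        pos = pos + intron + exon
        bounds.append(pos)
    bounds[-1] = length  # terminal exon runs to the gene end
    exon_offsets = [(bounds[i], bounds[i + 1]) for i in range(0, len(bounds) - 1, 2)]
    exons = []
    for a, b in exon_offsets:
        if strand == "+":
            exons.append(GenomicInterval(chrom, start + a, start + b, strand))
        else:
            exons.append(GenomicInterval(chrom, end - b, end - a, strand))
    return exons


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _umi_strings(rng: np.random.Generator, n: int, k: int) -> list[str]:
    idx = rng.integers(0, 4, size=(n, k))
    return ["".join(row) for row in _BASES[idx]]


def simulate_reads(
    truth: SimTruth,
    ann: AnnotationSet,
    n_molecules: int,
    seed: int,
) -> tuple[list[AlignedPair], ReadSetTruth]:
    """Generate aligned pairs for ``n_molecules`` unique molecules.

    Each molecule's read-2 first sequenced base sits at the gene's pause site
    with per-gene probability ``pause_fraction * pause_weight`` (clipped to
    0.95), else uniformly over the body downstream of the pause. Molecules are
    emitted ``1 + Poisson(pcr_duplication_rate)`` times with identical
    coordinates and UMI. Contaminant molecules land on small-RNA/rRNA loci.
    Minus-strand genes are handled mirror-symmetrically.
    """
    cfg = truth.config
    rng = _child_seed(cfg.seed, 2, seed)
    gene_ids = sorted(truth.genes)
    rst = ReadSetTruth(n_molecules=n_molecules, n_unique=0, n_pairs=0)
    if n_molecules == 0:
        return [], rst

    p_contam = cfg.contaminant_fraction
    p_rrna = cfg.rrna_fraction
    cat = rng.choice(3, size=n_molecules, p=[p_contam, p_rrna, 1 - p_contam - p_rrna])
    n_contam = int((cat == 0).sum())
    n_rrna = int((cat == 1).sum())
    n_gene = n_molecules - n_contam - n_rrna
    rst.n_contaminant, rst.n_rrna = n_contam, n_rrna

    weights = np.array([truth.genes[g].expression_weight for g in gene_ids])
    weights = weights / weights.sum()
    gene_pick = rng.choice(len(gene_ids), size=n_gene, p=weights) if gene_ids else np.array([], int)

    molecules: list[tuple[str, str, int]] = []  # (chrom, rna_strand, pos3)
    for gidx in gene_pick:
        gt = truth.genes[gene_ids[int(gidx)]]
        p_pause = min(0.95, cfg.pause_fraction * gt.pause_weight)
        if rng.random() < p_pause:
            off = gt.pause_offset
        else:
            off = int(rng.integers(gt.pause_offset, gt.length))
        pos3 = gt.tss + off if gt.strand == "+" else gt.tss - off
        molecules.append((gt.chrom, gt.strand, pos3))
        rst.reads_per_gene[gt.gene_id] = rst.reads_per_gene.get(gt.gene_id, 0) + 1
        if off == gt.pause_offset:
            rst.pause_reads_per_gene[gt.gene_id] = (
                rst.pause_reads_per_gene.get(gt.gene_id, 0) + 1
            )

    for loci, n_loc in ((ann.small_rna, n_contam), (ann.rrna, n_rrna)):
        if n_loc and not loci:
            raise ValueError("contaminant reads requested but no loci in annotation")
        for _ in range(n_loc):
            iv = loci[int(rng.integers(0, len(loci)))]
            pos3 = int(rng.integers(iv.start, iv.end))
            molecules.append((iv.chrom, iv.strand if iv.strand != "." else "+", pos3))

    order = rng.permutation(len(molecules))
    umis = _umi_strings(rng, len(molecules), cfg.umi_length)
    pairs: list[AlignedPair] = []
    keys: Counter = Counter()
    key_pos: dict[tuple, tuple[str, str, int]] = {}
    lo_f, hi_f = cfg.fragment_length_range
    lo_r, hi_r = cfg.read_length_range
    for out_i, mi in enumerate(order):
        chrom, strand, pos3 = molecules[int(mi)]
        umi = umis[int(mi)]
        frag = int(rng.integers(lo_f, hi_f + 1))
        # nascent RNA cannot extend upstream of its own 5' end / contig start
        frag = max(20, min(frag, pos3 + 1 if strand == "+" else 10**9))
        r2_len = min(int(rng.integers(lo_r, hi_r + 1)), frag)
        r1_len = min(int(rng.integers(lo_r, hi_r + 1)), frag)
        if strand == "+":
            # 3' end at pos3; molecule spans [pos3 - frag + 1, pos3]; read 2
            # starts at the 3' end and reads inward -> maps '-' ending at pos3
            r2_start, r2_end = pos3 - r2_len + 1, pos3 + 1
            f_start = pos3 - frag + 1
            r1_start, r1_end = f_start, f_start + r1_len
            r2_strand = "-"
        else:
            r2_start, r2_end = pos3, pos3 + r2_len
            f_end = pos3 + frag
            r1_start, r1_end = f_end - r1_len, f_end
            r2_strand = "+"
        if r1_start < 0 or r2_start < 0:
            raise ValueError("molecule clipped at contig start; enlarge margins")
        lead = int(rng.integers(1, 4)) if rng.random() < cfg.softclip_prob else 0
        key = (chrom, r2_strand, r1_start if r2_strand == "-" else r1_end - 1,
               pos3, umi)
        keys[key] += 1
        key_pos[key] = (chrom, strand, pos3)
        n_copies = 1 + int(rng.poisson(cfg.pcr_duplication_rate))
        for c in range(n_copies):
            pairs.append(
                AlignedPair(
                    chrom=chrom,
                    r1_start=r1_start,
                    r1_end=r1_end,
                    r2_start=r2_start,
                    r2_end=r2_end,
                    r2_strand=r2_strand,
                    umi=umi,
                    name=f"m{out_i:07d}.{c}_{umi}",
                    r2_leading_softclip=lead,
                )
            )
    unique: Counter = Counter()
    for key in keys:
        unique[key_pos[key]] += 1
    rst.unique_counts = dict(unique)
    rst.n_unique = len(keys)
    rst.n_pairs = len(pairs)
    return pairs, rst


# ---------------------------------------------------------------------------
# MNase fragments
# ---------------------------------------------------------------------------

def simulate_mnase(
    truth: SimTruth,
    n_fragments: int,
    dyad_loss: float | Mapping[str, float] = 0.0,
    seed: int = 0,
    length_target: int = 58,
    length_tol: int = 5,
    jitter_sd: float = 2.0,
) -> list[GenomicInterval]:
    """Subnucleosomal fragments around each gene's nucleosome center.

    Fragment midpoints sit at center-29 (TSS-proximal half in transcription
    order) or center+29 (distal half) with relative weights
    proximal : distal = 1 : (1 - dyad_loss), plus small Gaussian jitter.
    Lengths are uniform in ``length_target +/- length_tol``.
    ``dyad_loss`` may be a scalar or a per-gene mapping.
    """
    rng = _child_seed(truth.config.seed, 3, seed)
    gene_ids = sorted(truth.genes)
    if not gene_ids:
        return []
    frags: list[GenomicInterval] = []
    for _ in range(n_fragments):
        gid = gene_ids[int(rng.integers(0, len(gene_ids)))]
        gt = truth.genes[gid]
        loss = dyad_loss[gid] if isinstance(dyad_loss, Mapping) else float(dyad_loss)
        if not 0.0 <= loss <= 1.0:
            raise ValueError("dyad_loss must be in [0, 1]")
        p_distal = (1.0 - loss) / (2.0 - loss)
        distal = rng.random() < p_distal
        sign = 1 if gt.strand == "+" else -1
        mid = gt.nucleosome_center + sign * (29 if distal else -29)
        mid += int(round(rng.normal(0.0, jitter_sd)))
        length = int(rng.integers(length_target - length_tol, length_target + length_tol + 1))
        start = mid - length // 2
        frags.append(GenomicInterval(gt.chrom, start, start + length, ".", gid))
    return frags


# ---------------------------------------------------------------------------
# circadian time course
# ---------------------------------------------------------------------------

def simulate_timecourse(
    truth: SimTruth,
    ann: AnnotationSet,
    timepoints: Sequence[float] = (2, 6, 10, 14, 18, 22),
    seed: int = 0,
    baseline_exonic_reads: float = 1000.0,
    pause_reads: float = 400.0,
) -> dict[float, SingleNtSignal]:
    """Poisson-sampled per-timepoint signal with sinusoidal body transcription.

    Expected exonic body reads per gene follow
    ``baseline * (1 + amplitude * cos(2*pi*(t - phase)/24))`` for cycling
    genes and are flat otherwise. Genes flagged ``constitutive_pause`` keep
    the pause-site signal constant across timepoints while the body cycles.
    """
    if len(timepoints) < 2:
        raise ValueError("need >= 2 timepoints")
    cfg = truth.config
    rng = _child_seed(cfg.seed, 4, seed)
    genes = {g.gene_id: g for g in ann.genes}
    out: dict[float, SingleNtSignal] = {}
    for t in timepoints:
        sig = SingleNtSignal()
        for gid in sorted(truth.genes):
            gt = truth.genes[gid]
            gene = genes[gid]
            factor = 1.0
            if gt.cycling:
                factor = 1.0 + gt.amplitude * math.cos(2 * math.pi * (t - gt.phase) / 24.0)
            exonic_frac = gene.exonic_length() / gt.length
            lam_body = baseline_exonic_reads * factor / max(exonic_frac, 1e-9)
            n_body = int(rng.poisson(lam_body))
            offsets = rng.integers(gt.pause_offset + 1, gt.length, size=n_body)
            for off in offsets:
                sig.add(gt.chrom, gt.strand, gene.offset_to_genomic(int(off)))
            pause_factor = 1.0 if (gt.constitutive_pause or not gt.cycling) else factor
            n_pause = int(rng.poisson(pause_reads * gt.pause_weight * pause_factor))
            if n_pause:
                sig.add(gt.chrom, gt.strand, gt.pause_position, n_pause)
        out[t] = sig
    return out


# ---------------------------------------------------------------------------
# two-tissue / two-condition mode
# ---------------------------------------------------------------------------

_CLASSES = ("A_higher", "same", "B_higher")


def plant_concordance_classes(
    truth: SimTruth,
    seed: int = 0,
    fc: float = 4.0,
    class_probs: Sequence[float] | None = None,
) -> None:
    """Assign each gene a pause class and a body class from the 3x3 grid and
    set the corresponding per-tissue multipliers (fold change ``fc``)."""
    rng = _child_seed(truth.config.seed, 5, seed)
    p = np.full(3, 1 / 3) if class_probs is None else np.asarray(class_probs, float)
    for gid in sorted(truth.genes):
        gt = truth.genes[gid]
        pc, bc = (_CLASSES[i] for i in rng.choice(3, size=2, p=p / p.sum()))
        gt.pause_class, gt.body_class = pc, bc
        gt.pause_mult = (fc, 1.0) if pc == "A_higher" else (1.0, fc) if pc == "B_higher" else (1.0, 1.0)
        gt.body_mult = (fc, 1.0) if bc == "A_higher" else (1.0, fc) if bc == "B_higher" else (1.0, 1.0)


def simulate_two_tissue(
    truth: SimTruth,
    ann: AnnotationSet,
    seed: int = 0,
    pause_reads: float = 200.0,
    body_reads: float = 400.0,
) -> tuple[SingleNtSignal, SingleNtSignal]:
    """Poisson signals for two tissues using the planted class multipliers."""
    rng = _child_seed(truth.config.seed, 6, seed)
    genes = {g.gene_id: g for g in ann.genes}
    sig_a, sig_b = SingleNtSignal(), SingleNtSignal()
    for gid in sorted(truth.genes):
        gt = truth.genes[gid]
        gene = genes[gid]
        for sig, tix in ((sig_a, 0), (sig_b, 1)):
            n_p = int(rng.poisson(pause_reads * gt.pause_mult[tix]))
            if n_p:
                sig.add(gt.chrom, gt.strand, gt.pause_position, n_p)
            n_b = int(rng.poisson(body_reads * gt.body_mult[tix]))
            offsets = rng.integers(gt.pause_offset + 1, gt.length, size=n_b)
            for off in offsets:
                sig.add(gt.chrom, gt.strand, gene.offset_to_genomic(int(off)))
    return sig_a, sig_b
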