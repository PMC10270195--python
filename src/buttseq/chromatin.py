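"""Subnucleosomal MNase fragment analysis.

Fragments of ~58 bp are protected by one half of a partially unwrapped
histone dyad; their midpoints form two modes ~29 bp either side of the
nucleosome center. Centers are called by Gaussian-smoothing the midpoint
density, taking supported local maxima as dyad-half peaks, and pairing
half-peaks 40-80 bp apart; the call's center is the rounded mean of the pair.
A "-1 nucleosome" is any call whose canonical 147-bp footprint overlaps an
annotated TSS. Pause sites are then binned by their strand-aware distance
downstream of the nucleosome center.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import GeneModel, GenomicInterval
from .pause_detection import PauseSite

NUCLEOSOME_FOOTPRINT = 147  # canonical bp of DNA per nucleosome


def filter_fragments(
    fragments: Iterable[GenomicInterval], target: int = 58, tol: int = 5
) -> list[GenomicInterval]:
    """Keep fragments with length in ``[target - tol, target + tol]``."""
    return [f for f in fragments if target - tol <= len(f) <= target + tol]


@dataclass
class NucleosomeCall:
    chrom: str
    center: int
    fragment_count: int
    # dyad-half masses; oriented proximal/distal to the TSS once a gene is
    # attached, otherwise left/right in genomic order
    proximal_mass: float
    distal_mass: float
    overlaps_tss: bool = False
    gene_id: str = ""

    @property
    def footprint(self) -> tuple[int, int]:
        half = NUCLEOSOME_FOOTPRINT // 2
        return (self.center - half, self.center - half + NUCLEOSOME_FOOTPRINT)


def call_nucleosome_centers(
    fragments: Iterable[GenomicInterval],
    smoothing_bw: float = 15.0,
    min_support: int = 10,
    pair_separation: tuple[int, int] = (40, 80),
    half_peak_window: int = 15,
) -> list[NucleosomeCall]:
    """Call nucleosome centers from size-filtered fragment midpoints.

    Midpoint densities are smoothed with a Gaussian kernel (``smoothing_bw``
    bp); local maxima whose raw midpoint support within
    ``+/- half_peak_window`` bp reaches ``min_support`` become dyad-half
    peaks. Two half-peaks separated by 40-80 bp on the same chromosome are
    paired into one call (center = rounded mean); an unpaired half-peak
    becomes a call at its own position with one zero mass.
    """
    by_chrom: dict[str, list[int]] = {}
    for f in fragments:
        by_chrom.setdefault(f.chrom, []).append((f.start + f.end) // 2)
    calls: list[NucleosomeCall] = []
    lo_sep, hi_sep = pair_separation
    for chrom in sorted(by_chrom):
        mids = np.array(sorted(by_chrom[chrom]))
        lo, hi = mids.min() - 100, mids.max() + 101
        hist = np.bincount(mids - lo, minlength=hi - lo).astype(float)
        smooth = gaussian_filter1d(hist, sigma=smoothing_bw, mode="constant")
        peaks = _local_maxima(smooth)
        supported = []
        for p in peaks:
            support = int(hist[max(0, p - half_peak_window): p + half_peak_window + 1].sum())
            if support >= min_support:
                supported.append((p + lo, support))
        used = [False] * len(supported)
        for i, (p1, s1) in enumerate(supported):
            if used[i]:
                continue
            mate = None
            for j in range(i + 1, len(supported)):
                if used[j]:
                    continue
                p2 = supported[j][0]
                if lo_sep <= p2 - p1 <= hi_sep:
                    mate = j
                    break
                if p2 - p1 > hi_sep:
                    break
            if mate is not None:
                p2, s2 = supported[mate]
                used[i] = used[mate] = True
                calls.append(
                    NucleosomeCall(
                        chrom=chrom,
                        center=int(round((p1 + p2) / 2)),
                        fragment_count=s1 + s2,
                        proximal_mass=float(s1),
                        distal_mass=float(s2),
                    )
                )
            else:
                used[i] = True
                calls.append(
                    NucleosomeCall(
                        chrom=chrom,
                        center=p1,
                        fragment_count=s1,
                        proximal_mass=float(s1),
                        distal_mass=0.0,
                    )
                )
    return calls


def _local_maxima(arr: np.ndarray) -> list[int]:
    out = []
    for i in range(1, len(arr) - 1):
        if arr[i] > 0 and arr[i] >= arr[i - 1] and arr[i] > arr[i + 1]:
            out.append(i)
    return out


def minus1_nucleosomes(
    calls: Iterable[NucleosomeCall], genes: Iterable[GeneModel]
) -> list[NucleosomeCall]:
    """Calls whose 147-bp footprint overlaps an annotated TSS point.

    The overlapping call is flagged, annotated with the gene, and its dyad
    halves are oriented proximal/distal to that TSS (strand-aware).
    """
    genes = list(genes)
    out: list[NucleosomeCall] = []
    for call in calls:
        lo, hi = call.footprint
        for g in genes:
            if g.chrom == call.chrom and lo <= g.tss < hi:
                call.overlaps_tss = True
                call.gene_id = g.gene_id
                # masses were recorded left/right in genomic order; on '-'
                # genes the TSS-proximal half is the genomic-right one
                if g.strand == "-":
                    call.proximal_mass, call.distal_mass = (
                        call.distal_mass,
                        call.proximal_mass,
                    )
                out.append(call)
                break
    return out


def pause_nucleosome_distance(pause: PauseSite, nuc: NucleosomeCall) -> int:
    """Signed bp from nucleosome center to pause, positive = pause downstream
    of the center in transcription order (strand-aware)."""
    if pause.chrom != nuc.chrom:
        raise ValueError("pause and nucleosome on different chromosomes")
    delta = pause.position - nuc.center
    return delta if pause.strand == "+" else -delta


@dataclass(frozen=True)
class ClusterScheme:
    """Ordered distance bins (label, min_bp, max_bp), inclusive bounds."""

    bins: tuple[tuple[int, int, int], ...] = (
        (1, 80, 120),
        (2, 60, 79),
        (3, 40, 59),
        (4, 20, 39),
        (5, 0, 19),
    )

    def __post_init__(self) -> None:
        covered = sorted((lo, hi) for _, lo, hi in self.bins)
        for (a_lo, a_hi), (b_lo, b_hi) in zip(covered, covered[1:]):
            if b_lo != a_hi + 1:
                raise ValueError("cluster bins must be disjoint and contiguous")


def assign_cluster(distance: int, scheme: ClusterScheme | None = None) -> int | None:
    """Bin a pause-to-nucleosome distance; None when outside all bins."""
    scheme = scheme or ClusterScheme()
    for label, lo, hi in scheme.bins:
        if lo <= distance <= hi:
            return label
    return None
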