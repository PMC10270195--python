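"""Bootstrap pause-site calling near TSSs, per-gene filtering, motifs.

The caller scans the first ``search_region`` (default 200) transcribed bases
of each gene for single-nucleotide positions whose 3'-end count stands out
against a uniform null within a local window (default 100 bp, centered on the
candidate and clipped to the search region). The null is multinomial: the
window total T dropped i.i.d. uniformly over its W positions; the test
statistic of each resample is the maximum single-position count. The add-one
bootstrap p-value ``(1 + k) / (n_bootstraps + 1)`` never reaches the default
1e-5 threshold with 10,000 resamples, so whenever no resample maximum matches
the candidate (k = 0) an exact Bonferroni/binomial upper bound on the
multinomial-maximum tail, ``min(1, W * P(Binom(T, 1/W) >= c))``, is reported
in its place. The bound is conservative, so emitted sites are never
anti-conservative relative to the exact null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core import GeneModel, SingleNtSignal

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class PdaParams:
    """Pause-caller parameters (defaults follow the published settings:
    window 100, minimum intensity 5, 10,000 bootstraps, p threshold 1e-5,
    search region = first 200 bases downstream of the TSS)."""

    window: int = 100
    min_intensity: int = 5
    n_bootstraps: int = 10_000
    p_threshold: float = 1e-5
    search_region: int = 200

    def __post_init__(self) -> None:
        if min(self.window, self.min_intensity, self.n_bootstraps, self.search_region) <= 0:
            raise ValueError("all PDA parameters must be positive")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")


@dataclass(frozen=True)
class PauseSite:
    gene_id: str
    chrom: str
    strand: str
    position: int
    count: int
    p_value: float
    offset_from_tss: int


def bootstrap_null_max(
    total: int, width: int, n_boot: int, seed: int
) -> np.ndarray:
    """Sorted resample maxima under the uniform-multinomial null.

    ``total`` reads dropped i.i.d. uniformly over ``width`` positions,
    ``n_boot`` times; returns the per-resample maximum single-position count.
    Seeded deterministically from (seed, total, width) so results do not
    depend on candidate evaluation order.
    """
    ss = np.random.SeedSequence([int(seed), int(total), int(width)])
    rng = np.random.Generator(np.random.PCG64(ss))
    draws = rng.multinomial(total, np.full(width, 1.0 / width), size=n_boot)
    out = draws.max(axis=1)
    out.sort()
    return out


def max_tail_bound(count: int, total: int, width: int) -> float:
    """Bonferroni/binomial upper bound on P(max cell count >= ``count``)."""
    if count > total:
        return 0.0
    return float(min(1.0, width * stats.binom.sf(count - 1, total, 1.0 / width)))


class _NullCache:
    """Per-call cache of sorted null maxima keyed by (total, width)."""

    def __init__(self, n_boot: int, seed: int) -> None:
        self.n_boot = n_boot
        self.seed = seed
        self._store: dict[tuple[int, int], np.ndarray] = {}

    def tail_count(self, count: int, total: int, width: int) -> int:
        key = (total, width)
        if key not in self._store:
            self._store[key] = bootstrap_null_max(total, width, self.n_boot, self.seed)
        maxima = self._store[key]
        return int(self.n_boot - np.searchsorted(maxima, count, side="left"))


def detect_pauses(
    signal: SingleNtSignal,
    genes: Iterable[GeneModel],
    params: PdaParams | None = None,
    seed: int = 0,
) -> list[PauseSite]:
    """Call single-nucleotide pause sites in the TSS-proximal search region.

    For each candidate position with count >= ``min_intensity``, the bootstrap
    p is ``(1 + k) / (n_bootstraps + 1)`` where k counts resamples whose
    maximum reaches the candidate count; when k = 0 the exact binomial tail
    bound replaces the bootstrap floor. Sites with p <= ``p_threshold`` are
    emitted. Deterministic under a fixed seed.
    """
    params = params or PdaParams()
    cache = _NullCache(params.n_bootstraps, seed)
    half = params.window // 2
    sites: list[PauseSite] = []
    for gene in genes:
        counts = _tss_region_counts(signal, gene, params.search_region)
        candidates = np.nonzero(counts >= params.min_intensity)[0]
        for off in candidates.tolist():
            lo = max(0, off - half)
            hi = min(params.search_region, off + half)
            width = hi - lo
            total = int(counts[lo:hi].sum())
            c = int(counts[off])
            k = cache.tail_count(c, total, width)
            if k > 0:
                p = (1 + k) / (params.n_bootstraps + 1)
            else:
                p = max_tail_bound(c, total, width)
            if p <= params.p_threshold:
                sites.append(
                    PauseSite(
                        gene_id=gene.gene_id,
                        chrom=gene.chrom,
                        strand=gene.strand,
                        position=gene.offset_to_genomic(off),
                        count=c,
                        p_value=p,
                        offset_from_tss=off,
                    )
                )
    return sites


def _tss_region_counts(
    signal: SingleNtSignal, gene: GeneModel, search_region: int
) -> np.ndarray:
    """Per-base counts over the first ``search_region`` transcribed bases,
    indexed by offset from the TSS (strand-aware)."""
    if gene.strand == "+":
        arr = signal.array(gene.chrom, "+", gene.tss, gene.tss + search_region)
    else:
        arr = signal.array(
            gene.chrom, "-", gene.tss - search_region + 1, gene.tss + 1
        )[::-1]
    return arr


def top_pause_per_gene(sites: Iterable[PauseSite]) -> dict[str, PauseSite]:
    """One pause per gene: maximal count, ties broken toward the TSS."""
    best: dict[str, PauseSite] = {}
    for site in sites:
        cur = best.get(site.gene_id)
        if (
            cur is None
            or site.count > cur.count
            or (site.count == cur.count and site.offset_from_tss < cur.offset_from_tss)
        ):
            best[site.gene_id] = site
    return best


@dataclass
class PositionFrequencyMatrix:
    """Per-position base frequencies around pause sites (center = pause base).

    ``freqs`` is 4 x width in A/C/G/T row order; columns sum to 1.
    """

    freqs: np.ndarray
    flank: int

    @property
    def width(self) -> int:
        return self.freqs.shape[1]

    def column(self, offset: int) -> np.ndarray:
        """Frequencies at a signed offset from the pause base."""
        return self.freqs[:, offset + self.flank]

    def argmax_base(self, offset: int) -> str:
        return "ACGT"[int(np.argmax(self.column(offset)))]


def extract_pause_motif(
    sites: Iterable[PauseSite],
    genome: Mapping[str, str],
    flank: int = 10,
) -> PositionFrequencyMatrix:
    """Build a PFM from strand-corrected sequence ``+/- flank`` nt around each
    pause base (reverse-complemented for minus-strand sites). Sites within
    ``flank`` of a contig edge are skipped with a warning; sites on missing
    chromosomes raise."""
    if flank < 1:
        raise ValueError("flank must be >= 1")
    width = 2 * flank + 1
    counts = np.zeros((4, width), dtype=float)
    n_used = 0
    for site in sites:
        if site.chrom not in genome:
            raise KeyError(f"pause site on missing chromosome {site.chrom!r}")
        seq = genome[site.chrom]
        lo, hi = site.position - flank, site.position + flank + 1
        if lo < 0 or hi > len(seq):
            warnings.warn(f"pause at {site.chrom}:{site.position} within flank of contig edge; skipped")
            continue
        sub = seq[lo:hi].upper()
        if site.strand == "-":
            sub = sub.translate(_COMPLEMENT)[::-1]
        for j, base in enumerate(sub):
            if base in _BASE_INDEX:
                counts[_BASE_INDEX[base], j] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable pause sites for motif extraction")
    col_totals = counts.sum(axis=0)
    col_totals[col_totals == 0] = 1.0
    return PositionFrequencyMatrix(freqs=counts / col_totals, flank=flank)


def pause_shift(
    sites_a: Mapping[str, PauseSite], sites_b: Mapping[str, PauseSite]
) -> tuple[dict[str, int], float, int]:
    """Per-gene signed pause offset difference (B - A, bp; positive means the
    pause moved downstream). Returns (per-gene shifts, median shift, number of
    genes missing from either condition)."""
    shared = sorted(set(sites_a) & set(sites_b))
    missing = len(set(sites_a) ^ set(sites_b))
    shifts = {
        gid: sites_b[gid].offset_from_tss - sites_a[gid].offset_from_tss
        for gid in shared
    }
    median = float(np.median(list(shifts.values()))) if shifts else float("nan")
    return shifts, median, missing
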