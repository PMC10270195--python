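"""Region quantification, pausing indices, ECDF/KS comparison, and
median-of-ratios size-factor normalization.

Two pausing-index definitions are provided. The pause-anchored index uses the
called pause site of each gene: pause region = TSS to the pause (inclusive),
body = the ``body_length`` bases immediately downstream of the pause. The
fixed-window index uses a promoter window of -50/+200 around the TSS and the
remaining gene body. Both report a ratio of signal *densities* (counts per
bp), so regions of different lengths are comparable; ``raw_ratio=True``
switches to unnormalized count ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import special

from .core import GeneModel, GenomicInterval, SingleNtSignal
from .pause_detection import PauseSite


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def quantify(
    signal: SingleNtSignal, regions: Iterable[GenomicInterval]
) -> list[float]:
    """Per-region strand-matched sums of single-nucleotide signal.

    A region with strand '.' counts both strands.
    """
    out: list[float] = []
    for region in regions:
        strands = ("+", "-") if region.strand == "." else (region.strand,)
        out.append(
            sum(
                signal.window_sum(region.chrom, s, region.start, region.end)
                for s in strands
            )
        )
    return out


# ---------------------------------------------------------------------------
# pausing indices
# ---------------------------------------------------------------------------

@dataclass
class PausingIndexRecord:
    gene_id: str
    pause_region: GenomicInterval
    body_region: GenomicInterval
    pause_signal: float
    body_signal: float
    index: float  # nan when flagged
    flagged: bool = False
    flag_reason: str = ""


def _strand_region(gene: GeneModel, off_lo: int, off_hi: int) -> GenomicInterval:
    """Transcription-order offset range [off_lo, off_hi) -> genomic interval."""
    if gene.strand == "+":
        return GenomicInterval(
            gene.chrom, max(0, gene.tss + off_lo), gene.tss + off_hi, "+", gene.gene_id
        )
    return GenomicInterval(
        gene.chrom, max(0, gene.tss - off_hi + 1), gene.tss - off_lo + 1, "-", gene.gene_id
    )


def pausing_index_anchored(
    gene: GeneModel,
    pause: PauseSite,
    signal: SingleNtSignal,
    body_length: int = 1000,
    raw_ratio: bool = False,
) -> PausingIndexRecord:
    """Pause-anchored index: [TSS, pause] vs the ``body_length`` bases
    downstream of the pause (truncated at the TES with a flag when the gene
    ends first). Genes with zero body signal are flagged and excluded from
    downstream ECDFs."""
    if pause.gene_id != gene.gene_id:
        raise ValueError("pause site does not belong to gene")
    off = pause.offset_from_tss
    if off < 1:
        raise ValueError("pause offset must be >= 1")
    pause_region = _strand_region(gene, 0, off + 1)
    body_end = off + 1 + body_length
    truncated = body_end > gene.length
    body_end = min(body_end, gene.length)
    body_region = _strand_region(gene, off + 1, body_end)
    return _index_record(gene, pause_region, body_region, signal, raw_ratio,
                         truncated=truncated)


def pausing_index_fixed(
    gene: GeneModel,
    signal: SingleNtSignal,
    promoter: tuple[int, int] = (-50, 200),
    raw_ratio: bool = False,
) -> PausingIndexRecord:
    """Fixed-window index: promoter [TSS-50, TSS+200) vs gene body
    [TSS+200, TES], strand-mirrored."""
    lo, hi = promoter
    if gene.length <= hi + 50:
        raise ValueError(f"gene {gene.gene_id} too short for fixed promoter window")
    pause_region = _strand_region(gene, lo, hi)
    body_region = _strand_region(gene, hi, gene.length)
    return _index_record(gene, pause_region, body_region, signal, raw_ratio)


def _index_record(
    gene: GeneModel,
    pause_region: GenomicInterval,
    body_region: GenomicInterval,
    signal: SingleNtSignal,
    raw_ratio: bool,
    truncated: bool = False,
) -> PausingIndexRecord:
    pause_sig = signal.window_sum(gene.chrom, gene.strand, pause_region.start, pause_region.end)
    body_sig = signal.window_sum(gene.chrom, gene.strand, body_region.start, body_region.end)
    flagged = body_sig == 0 or pause_sig == 0
    reason = "zero body signal" if body_sig == 0 else ("zero pause signal" if pause_sig == 0 else "")
    if flagged:
        index = float("nan")
    elif raw_ratio:
        index = pause_sig / body_sig
    else:
        index = (pause_sig / len(pause_region)) / (body_sig / len(body_region))
    return PausingIndexRecord(
        gene_id=gene.gene_id,
        pause_region=pause_region,
        body_region=body_region,
        pause_signal=pause_sig,
        body_signal=body_sig,
        index=index,
        flagged=flagged,
        flag_reason=reason or ("body truncated at TES" if truncated else ""),
    )


# ---------------------------------------------------------------------------
# ECDF / KS
# ---------------------------------------------------------------------------

class Ecdf:
    """Right-continuous empirical CDF, evaluable at any point."""

    def __init__(self, values: Sequence[float]) -> None:
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise ValueError("ECDF of an empty sample is undefined")
        self.support = np.sort(arr)
        self.n = arr.size

    def __call__(self, x: float | np.ndarray) -> float | np.ndarray:
        out = np.searchsorted(self.support, x, side="right") / self.n
        return float(out) if np.isscalar(x) else out


@dataclass(frozen=True)
class KsResult:
    D: float
    p_value: float
    n_x: int
    n_y: int


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> KsResult:
    """Two-sample Kolmogorov-Smirnov: exact D on the pooled sample points,
    p from the asymptotic Kolmogorov distribution at effective sample size
    ``n_x * n_y / (n_x + n_y)``."""
    xs = np.sort(np.asarray(x, dtype=float))
    ys = np.sort(np.asarray(y, dtype=float))
    if xs.size == 0 or ys.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([xs, ys])
    fx = np.searchsorted(xs, pooled, side="right") / xs.size
    fy = np.searchsorted(ys, pooled, side="right") / ys.size
    d = float(np.max(np.abs(fx - fy)))
    ne = xs.size * ys.size / (xs.size + ys.size)
    p = float(np.clip(special.kolmogorov(np.sqrt(ne) * d), 0.0, 1.0))
    return KsResult(D=d, p_value=max(p, np.finfo(float).tiny), n_x=xs.size, n_y=ys.size)


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors over a features x samples count matrix.

    The reference is the per-feature geometric mean across samples, computed
    over features with all-positive counts; each sample's factor is the median
    over those features of count / reference.
    """
    mat = np.asarray(counts, dtype=float)
    if mat.ndim != 2:
        raise ValueError("counts must be a 2-D features x samples matrix")
    positive = np.all(mat > 0, axis=1)
    if not positive.any():
        raise ValueError("no feature with all-positive counts across samples")
    logs = np.log(mat[positive])
    log_ref = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_ref, axis=0))
    return factors


def normalize_signal(signal: SingleNtSignal, factor: float) -> SingleNtSignal:
    """Divide every count by a positive size factor."""
    return signal.scale(factor)
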