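"""Anchored and scaled metagene matrices with trimming, log transform, and
percentile-bootstrap confidence bands."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .core import GeneModel, SingleNtSignal


@dataclass
class MetageneMatrix:
    """Rows = genes (stable, recorded order), columns = single-base bins.

    In reference-point ("tss") mode column ``anchor_col`` (= upstream) is the
    TSS base and the matrix is ``upstream + downstream`` wide. In
    scale-region mode gene bodies are linearly rescaled to a fixed width.
    """

    matrix: np.ndarray
    row_ids: list[str]
    mode: str
    anchor_col: int = 0
    padded_rows: list[str] = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.matrix.shape[1]


@dataclass
class MetageneSummary:
    """Per-column mean with a percentile-bootstrap confidence band."""

    position: np.ndarray  # signed offset from anchor (tss mode) or bin index
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_regions: int


def build_matrix(
    signal: SingleNtSignal,
    genes: Iterable[GeneModel],
    mode: str = "tss",
    upstream: int = 200,
    downstream: int = 1000,
    min_gene_length: int = 5000,
    plus_strand_only: bool = False,
    scale_width: int = 1000,
) -> MetageneMatrix:
    """Strand-aware per-gene signal rows at single-base resolution.

    ``mode="tss"`` anchors rows at the TSS (``upstream`` bases before it,
    ``downstream`` after); signal beyond the TES is zeroed and the row is
    flagged as padded. ``mode="scale"`` linearly rescales each gene body to
    ``scale_width`` bins. Genes with length <= ``min_gene_length`` are
    dropped, as are minus-strand genes when ``plus_strand_only`` is set.
    """
    if mode not in ("tss", "scale"):
        raise ValueError(f"unknown metagene mode {mode!r}")
    kept = [
        g for g in genes
        if g.length > min_gene_length and (not plus_strand_only or g.strand == "+")
    ]
    rows: list[np.ndarray] = []
    row_ids: list[str] = []
    padded: list[str] = []
    for g in kept:
        if mode == "tss":
            row = _tss_row(signal, g, upstream, downstream)
            if g.length < downstream:
                row[upstream + g.length:] = 0.0
                padded.append(g.gene_id)
        else:
            body = _body_counts(signal, g)
            row = np.interp(
                np.linspace(0, len(body) - 1, scale_width), np.arange(len(body)), body
            )
        rows.append(row)
        row_ids.append(g.gene_id)
    width = (upstream + downstream) if mode == "tss" else scale_width
    matrix = np.vstack(rows) if rows else np.zeros((0, width))
    return MetageneMatrix(
        matrix=matrix,
        row_ids=row_ids,
        mode=mode,
        anchor_col=upstream if mode == "tss" else 0,
        padded_rows=padded,
    )


def _tss_row(signal: SingleNtSignal, gene: GeneModel, upstream: int, downstream: int) -> np.ndarray:
    if gene.strand == "+":
        start = gene.tss - upstream
        arr = signal.array(gene.chrom, "+", max(0, start), gene.tss + downstream)
        if start < 0:
            arr = np.concatenate([np.zeros(-start), arr])
        return arr
    start = gene.tss - downstream + 1
    arr = signal.array(gene.chrom, "-", max(0, start), gene.tss + upstream + 1)
    if start < 0:
        arr = np.concatenate([np.zeros(-start), arr])
    return arr[::-1]


def _body_counts(signal: SingleNtSignal, gene: GeneModel) -> np.ndarray:
    arr = signal.array(gene.chrom, gene.strand, gene.start, gene.end)
    return arr if gene.strand == "+" else arr[::-1]


def summarize(
    matrix: MetageneMatrix,
    trim_fraction: float = 0.001,
    pseudocount: float = 1.0,
    n_boot: int = 10_000,
    ci: float = 0.95,
    seed: int = 0,
    log_transform: bool = True,
) -> MetageneSummary:
    """Trim outlier rows, transform, and bootstrap the per-column mean.

    Rows are ranked by row total; ``ceil(trim_fraction * N)`` rows are removed
    from each tail. With ``log_transform`` the values become
    ``log2(x + pseudocount)``. The confidence band is the percentile bootstrap
    over row resampling with ``n_boot`` repetitions.
    """
    X = matrix.matrix
    n = X.shape[0]
    k = math.ceil(trim_fraction * n)
    if n - 2 * k < 10:
        raise ValueError(f"too few rows after trimming ({n} rows, trim {k} per tail)")
    order = np.argsort(X.sum(axis=1), kind="stable")
    keep = order[k : n - k] if k else order
    X = X[np.sort(keep)]
    if log_transform:
        X = np.log2(X + pseudocount)
    m = X.shape[0]
    mean = X.mean(axis=0)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(int(seed))))
    weights = rng.multinomial(m, np.full(m, 1.0 / m), size=n_boot)
    boot_means = (weights @ X) / m
    alpha = (1.0 - ci) / 2.0
    lower = np.quantile(boot_means, alpha, axis=0)
    upper = np.quantile(boot_means, 1.0 - alpha, axis=0)
    if matrix.mode == "tss":
        position = np.arange(X.shape[1]) - matrix.anchor_col
    else:
        position = np.arange(X.shape[1])
    return MetageneSummary(
        position=position, mean=mean, lower=lower, upper=upper, n_regions=m
    )
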