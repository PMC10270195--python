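"""Two-condition pause/elongation concordance and circadian quantification.

Concordance classification compares, per gene, the size-factor-normalized
signal in the pause region (TSS to the merged pause anchor) and the
elongation region (a fixed stretch downstream of the anchor) between two
conditions, placing each gene in one cell of a 3x3 grid
({A_higher, same, B_higher} for pause x body). The decision rule is a
symmetric fold-change threshold with a minimum-count filter; the thresholds
are reported alongside the grid because the class fractions depend on them.

Circadian quantification sums exon-only signal per gene per timepoint
(intron signal is excluded to avoid nascent-splicing artifacts), normalizes
across timepoints with median-of-ratios size factors, and reports per-gene
peak/trough timepoints after row-wise peak normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AnnotationSet, GeneModel, SingleNtSignal
from .metrics import quantify, size_factors
from .pause_detection import PauseSite

CLASSES = ("A_higher", "same", "B_higher")


# ---------------------------------------------------------------------------
# pause-peak merging
# ---------------------------------------------------------------------------

def merge_pause_peaks(
    sites_a: Mapping[str, PauseSite], sites_b: Mapping[str, PauseSite]
) -> dict[str, tuple[PauseSite, str]]:
    """Unified per-gene pause anchor across two conditions.

    When both conditions called a site the anchor is the one with the larger
    count (tie -> TSS-proximal); otherwise the single available site is used.
    The provenance tag is "both", "A_only" or "B_only".
    """
    merged: dict[str, tuple[PauseSite, str]] = {}
    for gid in sorted(set(sites_a) | set(sites_b)):
        a, b = sites_a.get(gid), sites_b.get(gid)
        if a is not None and b is not None:
            if a.count > b.count:
                site = a
            elif b.count > a.count:
                site = b
            else:
                site = a if a.offset_from_tss <= b.offset_from_tss else b
            merged[gid] = (site, "both")
        elif a is not None:
            merged[gid] = (a, "A_only")
        else:
            merged[gid] = (b, "B_only")
    return merged


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceRecord:
    gene_id: str
    pause_class: str
    body_class: str
    pause_a: float
    pause_b: float
    body_a: float
    body_b: float

    @property
    def cell(self) -> tuple[str, str]:
        return (self.pause_class, self.body_class)


@dataclass
class ConcordanceResult:
    records: list[ConcordanceRecord]
    grid: pd.DataFrame  # 3x3 counts, rows = pause class, cols = body class
    fractions: dict[str, float]  # concordant / single_discordant / double_discordant
    n_excluded: int
    fc_threshold: float
    min_count: float


def _classify(norm_a: float, norm_b: float, fc: float) -> str:
    if norm_b == 0:
        return "A_higher" if norm_a > 0 else "same"
    ratio = norm_a / norm_b
    if ratio >= fc:
        return "A_higher"
    if ratio <= 1.0 / fc:
        return "B_higher"
    return "same"


def concordance_classify(
    signal_a: SingleNtSignal,
    signal_b: SingleNtSignal,
    anchors: Mapping[str, tuple[PauseSite, str]] | Mapping[str, PauseSite],
    genes: Iterable[GeneModel],
    factors: Sequence[float],
    body_length: int = 1000,
    fc_threshold: float = 2.0,
    min_count: float = 10.0,
) -> ConcordanceResult:
    """Classify genes into the 3x3 pause/body concordance grid.

    ``factors`` are the two conditions' size factors (computed upstream over
    shared regions of interest). A gene region is usable when at least one
    condition reaches ``min_count`` raw counts there; genes failing that in
    either region are excluded and counted.
    """
    if fc_threshold < 1.0:
        raise ValueError("fc_threshold must be >= 1")
    fa, fb = float(factors[0]), float(factors[1])
    gene_map = {g.gene_id: g for g in genes}
    records: list[ConcordanceRecord] = []
    n_excluded = 0
    for gid in sorted(anchors):
        entry = anchors[gid]
        site = entry[0] if isinstance(entry, tuple) else entry
        gene = gene_map.get(gid)
        if gene is None:
            continue
        off = site.offset_from_tss
        sign = 1 if gene.strand == "+" else -1
        tss = gene.tss
        p_lo, p_hi = sorted((tss, tss + sign * off))
        b_lo, b_hi = sorted((tss + sign * (off + 1), tss + sign * (off + body_length)))
        vals = {}
        for label, (lo, hi) in (("pause", (p_lo, p_hi + 1)), ("body", (b_lo, b_hi + 1))):
            ca = signal_a.window_sum(gene.chrom, gene.strand, lo, hi)
            cb = signal_b.window_sum(gene.chrom, gene.strand, lo, hi)
            vals[label] = (ca, cb)
        if any(max(ca, cb) < min_count for ca, cb in vals.values()):
            n_excluded += 1
            continue
        pa, pb = vals["pause"][0] / fa, vals["pause"][1] / fb
        ba, bb = vals["body"][0] / fa, vals["body"][1] / fb
        records.append(
            ConcordanceRecord(
                gene_id=gid,
                pause_class=_classify(pa, pb, fc_threshold),
                body_class=_classify(ba, bb, fc_threshold),
                pause_a=pa, pause_b=pb, body_a=ba, body_b=bb,
            )
        )
    if not records:
        raise ValueError("all genes excluded; nothing to classify")
    grid = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES))
    for rec in records:
        grid.loc[rec.pause_class, rec.body_class] += 1
    n = len(records)
    concordant = sum(grid.loc[c, c] for c in CLASSES)
    double = grid.loc["A_higher", "B_higher"] + grid.loc["B_higher", "A_higher"]
    fractions = {
        "concordant": concordant / n,
        "single_discordant": (n - concordant - double) / n,
        "double_discordant": double / n,
    }
    return ConcordanceResult(
        records=records,
        grid=grid,
        fractions=fractions,
        n_excluded=n_excluded,
        fc_threshold=fc_threshold,
        min_count=min_count,
    )


# ---------------------------------------------------------------------------
# circadian quantification
# ---------------------------------------------------------------------------

def circadian_quantify(
    signals: Mapping[float, SingleNtSignal],
    genes: Iterable[GeneModel],
    size_normalize: bool = True,
) -> pd.DataFrame:
    """Genes x timepoints matrix of exon-only signal sums.

    Intronic signal contributes nothing. With ``size_normalize`` each
    timepoint column is divided by its median-of-ratios size factor.
    """
    if len(signals) < 2:
        raise ValueError("need >= 2 timepoints")
    genes = list(genes)
    tps = sorted(signals)
    data = {}
    for t in tps:
        sig = signals[t]
        col = []
        for g in genes:
            col.append(sum(quantify(sig, g.exons)))
        data[t] = col
    mat = pd.DataFrame(data, index=[g.gene_id for g in genes], dtype=float)
    if size_normalize:
        factors = size_factors(mat.to_numpy())
        mat = mat / factors
    return mat


def normalize_to_peak(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise division by the row maximum; all-zero rows are dropped."""
    row_max = matrix.max(axis=1)
    kept = matrix.loc[row_max > 0]
    return kept.div(row_max[row_max > 0], axis=0)


def peak_trough(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene peak/trough timepoints and peak-to-trough amplitude.

    Amplitude is inf-flagged (``amplitude_inf`` True, value NaN) when the
    trough is exactly zero.
    """
    peak_tp = matrix.idxmax(axis=1)
    trough_tp = matrix.idxmin(axis=1)
    peak = matrix.max(axis=1)
    trough = matrix.min(axis=1)
    inf_mask = trough == 0
    amp = peak / trough.where(~inf_mask)
    return pd.DataFrame(
        {
            "peak_timepoint": peak_tp,
            "trough_timepoint": trough_tp,
            "amplitude": amp,
            "amplitude_inf": inf_mask,
        }
    )
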