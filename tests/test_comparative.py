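"""Pause-peak merging, concordance grid, circadian quantification."""

import numpy as np
import pandas as pd
import pytest

import buttseq as b
from buttseq.core import GeneModel, GenomicInterval, SingleNtSignal
from buttseq.pause_detection import PauseSite
from buttseq.preprocess import tss_window_interval


def _site(gid, off, count, chrom="c", strand="+", tss=0):
    pos = tss + off if strand == "+" else tss - off
    return PauseSite(gid, chrom, strand, pos, count, 1e-9, off)


class TestMerge:
    def test_same_position_both(self):
        a = {"g": _site("g", 50, 30)}
        merged = b.merge_pause_peaks(a, {"g": _site("g", 50, 30)})
        site, tag = merged["g"]
        assert site.offset_from_tss == 50 and tag == "both"

    def test_single_condition_used(self):
        merged = b.merge_pause_peaks({"g": _site("g", 50, 30)}, {})
        assert merged["g"][1] == "A_only"
        merged = b.merge_pause_peaks({}, {"g": _site("g", 70, 12)})
        assert merged["g"][1] == "B_only"

    def test_larger_count_wins(self):
        merged = b.merge_pause_peaks(
            {"g": _site("g", 50, 30)}, {"g": _site("g", 80, 12)}
        )
        assert merged["g"][0].offset_from_tss == 50

    def test_tie_breaks_toward_tss(self):
        merged = b.merge_pause_peaks(
            {"g": _site("g", 80, 30)}, {"g": _site("g", 50, 30)}
        )
        assert merged["g"][0].offset_from_tss == 50


def _gene(gid="g", length=3000):
    return GeneModel(gid, "c", "+", [GenomicInterval("c", 0, length, "+")])


def _signal_for(pause_count, body_count, gene, off=50):
    sig = SingleNtSignal()
    sig.add("c", "+", off, pause_count)
    per = body_count / 1000
    for p in range(off + 1, off + 1001):
        sig.add("c", "+", p, per)
    return sig


class TestConcordance:
    def test_identical_conditions_all_same(self):
        gene = _gene()
        sig = _signal_for(100, 300, gene)
        anchors = {"g": (_site("g", 50, 100), "both")}
        res = b.concordance_classify(sig, sig, anchors, [gene], [1.0, 1.0])
        assert res.grid.loc["same", "same"] == 1
        assert res.fractions["concordant"] == 1.0

    def test_threshold_one_requires_exact_equality(self):
        gene = _gene()
        a = _signal_for(100, 300, gene)
        bb = _signal_for(101, 300, gene)
        anchors = {"g": (_site("g", 50, 100), "both")}
        res = b.concordance_classify(a, bb, anchors, [gene], [1.0, 1.0], fc_threshold=1.0)
        # any inequality is classified at fc_threshold = 1
        assert res.records[0].pause_class == "B_higher"

    def test_min_count_exclusion(self):
        gene = _gene()
        a = _signal_for(3, 4, gene)
        anchors = {"g": (_site("g", 50, 3), "both")}
        with pytest.raises(ValueError):
            b.concordance_classify(a, a, anchors, [gene], [1.0, 1.0], min_count=10)

    def test_antisymmetric_under_swap(self, small_sim):
        _, ann, _, truth = small_sim
        b.plant_concordance_classes(truth, seed=51, fc=4.0)
        sa, sb = b.simulate_two_tissue(truth, ann, seed=52)
        windows = [tss_window_interval(g) for g in ann.genes]
        counts = np.column_stack([b.quantify(sa, windows), b.quantify(sb, windows)])
        f = b.size_factors(counts)
        anchors = {
            g: (_site(g, t.pause_offset, 100, t.chrom, t.strand, t.tss), "both")
            for g, t in truth.genes.items()
        }
        r1 = b.concordance_classify(sa, sb, anchors, ann.genes, f)
        r2 = b.concordance_classify(sb, sa, anchors, ann.genes, f[::-1])
        flip = {"A_higher": "B_higher", "same": "same", "B_higher": "A_higher"}
        for rec1, rec2 in zip(r1.records, r2.records):
            assert rec2.pause_class == flip[rec1.pause_class]
            assert rec2.body_class == flip[rec1.body_class]
        assert sum(r1.fractions.values()) == pytest.approx(1.0)

    def test_planted_classes_recovered(self, small_sim):
        _, ann, _, truth = small_sim
        b.plant_concordance_classes(truth, seed=53, fc=4.0)
        sa, sb = b.simulate_two_tissue(truth, ann, seed=54)
        windows = [tss_window_interval(g) for g in ann.genes]
        counts = np.column_stack([b.quantify(sa, windows), b.quantify(sb, windows)])
        anchors = {
            g: (_site(g, t.pause_offset, 100, t.chrom, t.strand, t.tss), "both")
            for g, t in truth.genes.items()
        }
        res = b.concordance_classify(sa, sb, anchors, ann.genes, b.size_factors(counts))
        correct = sum(
            (r.pause_class, r.body_class)
            == (truth.genes[r.gene_id].pause_class, truth.genes[r.gene_id].body_class)
            for r in res.records
        )
        assert correct / len(res.records) >= 0.9


class TestCircadian:
    def _two_exon_gene(self):
        return GeneModel(
            "g", "c", "+",
            [GenomicInterval("c", 0, 400, "+"), GenomicInterval("c", 900, 1400, "+")],
        )

    def test_intron_signal_excluded(self):
        gene = self._two_exon_gene()
        sig0, sig1 = SingleNtSignal(), SingleNtSignal()
        sig0.add("c", "+", 100, 10)
        sig1.add("c", "+", 100, 10)
        sig1.add("c", "+", 600, 500)  # intronic spike must contribute nothing
        mat = b.circadian_quantify({2.0: sig0, 14.0: sig1}, [gene], size_normalize=False)
        assert mat.loc["g", 2.0] == mat.loc["g", 14.0] == 10.0

    def test_matches_quantify_over_exons(self, small_sim):
        _, ann, _, truth = small_sim
        tc = b.simulate_timecourse(truth, ann, seed=61, baseline_exonic_reads=100)
        mat = b.circadian_quantify(tc, ann.genes, size_normalize=False)
        g = ann.genes[0]
        for t in tc:
            assert mat.loc[g.gene_id, t] == sum(b.quantify(tc[t], g.exons))

    def test_normalize_to_peak(self):
        mat = pd.DataFrame(
            {2: [10, 5, 0], 6: [20, 5, 0], 10: [50, 5, 0], 14: [40, 5, 0]},
            index=["a", "const", "zero"], dtype=float,
        )
        norm = b.normalize_to_peak(mat)
        assert list(norm.loc["a"]) == [0.2, 0.4, 1.0, 0.8]
        assert (norm.loc["const"] == 1.0).all()
        assert "zero" not in norm.index
        # idempotent
        pd.testing.assert_frame_equal(b.normalize_to_peak(norm), norm)

    def test_peak_trough(self):
        mat = pd.DataFrame({2: [1.0, 5.0], 14: [4.0, 5.0]}, index=["cyc", "flat"])
        pt = b.peak_trough(mat)
        assert pt.loc["cyc", "peak_timepoint"] == 14
        assert pt.loc["cyc", "amplitude"] == 4.0
        assert pt.loc["flat", "amplitude"] == 1.0

    def test_zero_trough_inf_flag(self):
        mat = pd.DataFrame({2: [0.0], 14: [4.0]}, index=["g"])
        pt = b.peak_trough(mat)
        assert bool(pt.loc["g", "amplitude_inf"]) and np.isnan(pt.loc["g", "amplitude"])
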