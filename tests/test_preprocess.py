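"""Dedup, soft-clip handling, single-nucleotide conversion, masking and
TSS-window restriction."""

import pytest
from hypothesis import given, settings, strategies as st

import buttseq as b
from buttseq.core import AlignedPair, AnnotationSet, GeneModel, GenomicInterval
from buttseq.preprocess import dedup_key


def make_pair(r2_strand="-", r1=(900, 950), r2=(1000, 1050), umi="AAAAAAAA",
              name="p", chrom="c", lead=0):
    return AlignedPair(
        chrom=chrom, r1_start=r1[0], r1_end=r1[1], r2_start=r2[0], r2_end=r2[1],
        r2_strand=r2_strand, umi=umi, name=name, r2_leading_softclip=lead,
    )


class TestSoftclips:
    def test_anchor_unchanged_by_clip(self):
        """Clipped bases have no reference coordinate, so the 3'-end anchor
        is the aligned end adjacent to the leading clip regardless of clip."""
        clipped = make_pair(r2_strand="+", lead=3)
        stripped = b.strip_softclips(clipped)
        assert stripped.r2_leading_softclip == 0 and stripped.softclips_stripped
        assert b.to_single_nucleotide(stripped) == b.to_single_nucleotide(
            b.strip_softclips(make_pair(r2_strand="+", lead=0))
        )

    def test_identity_when_unclipped(self):
        p = make_pair()
        q = b.strip_softclips(p)
        assert (q.r2_start, q.r2_end, q.r1_start) == (p.r2_start, p.r2_end, p.r1_start)


class TestDedup:
    def test_same_key_collapses(self):
        kept = b.deduplicate([make_pair(name="a"), make_pair(name="b")])
        assert len(kept) == 1 and kept[0].name == "a"

    def test_distinct_umis_kept(self):
        kept = b.deduplicate(
            [make_pair(umi="AAAAAAAA"), make_pair(umi="AAAAAAAT")]
        )
        assert len(kept) == 2

    def test_idempotent(self, read_sim):
        pairs, _ = read_sim
        once = b.deduplicate(pairs)
        assert b.deduplicate(once) == once

    def test_kept_equals_distinct_molecules(self, read_sim):
        pairs, rst = read_sim
        stats = b.DedupStats()
        kept = b.deduplicate(pairs, stats)
        assert stats.kept == rst.n_unique
        assert stats.kept + stats.removed == rst.n_pairs
        assert len({dedup_key(p) for p in pairs}) == stats.kept


class TestSingleNucleotide:
    def test_read2_plus_takes_start(self):
        chrom, strand, pos = b.to_single_nucleotide(make_pair(r2_strand="+"))
        assert (pos, strand) == (1000, "-")  # RNA antisense to read-2 mapping

    def test_read2_minus_takes_last_base(self):
        chrom, strand, pos = b.to_single_nucleotide(make_pair(r2_strand="-"))
        assert (pos, strand) == (1049, "+")

    def test_same_convention_flips_strand_only(self):
        p = make_pair(r2_strand="-")
        opp = b.to_single_nucleotide(p, "opposite")
        same = b.to_single_nucleotide(p, "same")
        assert opp[2] == same[2] and opp[1] == "+" and same[1] == "-"

    def test_signal_total_conserved(self, read_sim):
        pairs, rst = read_sim
        kept = b.deduplicate(pairs)
        sig = b.build_signal(kept)
        assert sig.total() == len(kept) == rst.n_unique


def _tiny_annotation():
    gene = GeneModel("g", "c", "+", [GenomicInterval("c", 0, 2000, "+")])
    return AnnotationSet(
        genes=[gene],
        small_rna=[GenomicInterval("c", 100, 150, "+")],
        rrna=[GenomicInterval("c", 500, 600, "+")],
    )


class TestMasking:
    def test_inside_interval_removed_boundary_kept(self):
        ann = _tiny_annotation()
        sig = b.SingleNtSignal()
        for pos in (99, 100, 149, 150):
            sig.add("c", "+", pos)
        masked = b.mask_contaminants(sig, ann)
        kept = sorted(masked.as_dict()[("c", "+")])
        assert kept == [99, 150]  # half-open [100, 150)

    def test_strand_matched(self):
        ann = _tiny_annotation()
        sig = b.SingleNtSignal()
        sig.add("c", "-", 120)  # opposite strand of the snoRNA
        assert b.mask_contaminants(sig, ann) == sig

    def test_empty_mask_identity(self):
        ann = AnnotationSet(genes=_tiny_annotation().genes)
        sig = b.SingleNtSignal()
        sig.add("c", "+", 100)
        assert b.mask_contaminants(sig, ann) == sig

    def test_contamination_fractions(self):
        ann = _tiny_annotation()
        sig = b.SingleNtSignal()
        sig.add("c", "+", 120, 40)   # small RNA
        sig.add("c", "+", 550, 10)   # rRNA
        sig.add("c", "+", 1500, 50)  # clean
        rep = b.contamination_report(sig, ann)
        assert rep == {"small_rna_fraction": 0.4, "rrna_fraction": 0.1}

    def test_simulated_contaminant_fraction_recovered(self, small_sim):
        cfg, ann, _, truth = small_sim
        pairs, _ = b.simulate_reads(truth, ann, 20_000, seed=301)
        sig = b.build_signal(b.deduplicate(pairs))
        rep = b.contamination_report(sig, ann)
        assert rep["small_rna_fraction"] == pytest.approx(
            cfg.contaminant_fraction, abs=0.015
        )


class TestTssWindows:
    def test_plus_gene_window(self):
        gene = GeneModel("g", "c", "+", [GenomicInterval("c", 0, 2000, "+")])
        sig = b.SingleNtSignal()
        sig.add("c", "+", 0)
        sig.add("c", "+", 199)
        sig.add("c", "+", 200)  # outside
        [(win, sl)] = b.restrict_to_tss_windows(sig, [gene])
        assert (win.region.start, win.region.end) == (0, 200)
        assert sorted(sl.as_dict()[("c", "+")]) == [0, 199]

    def test_minus_gene_window_mirrored(self):
        gene = GeneModel("g", "c", "-", [GenomicInterval("c", 0, 501, "-")])
        sig = b.SingleNtSignal()
        sig.add("c", "-", 500)  # TSS itself
        sig.add("c", "-", 301)
        sig.add("c", "-", 300)  # outside the first 200 transcribed bases
        [(win, sl)] = b.restrict_to_tss_windows(sig, [gene])
        assert (win.region.start, win.region.end) == (301, 501)
        assert sorted(sl.as_dict()[("c", "-")]) == [301, 500]

    def test_overlapping_same_strand_genes_merged(self):
        g1 = GeneModel("g1", "c", "+", [GenomicInterval("c", 0, 2000, "+")])
        g2 = GeneModel("g2", "c", "+", [GenomicInterval("c", 100, 2100, "+")])
        sig = b.SingleNtSignal()
        [(win, _)] = b.restrict_to_tss_windows(sig, [g1, g2])
        assert (win.region.start, win.region.end) == (0, 300)
        assert sorted(win.gene_ids) == ["g1", "g2"]


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(0, 50), st.integers(0, 3), st.text("ACGT", min_size=2, max_size=2)),
        min_size=1, max_size=30,
    )
)
def test_dedup_key_semantics(entries):
    """Dedup keeps exactly one pair per (positions, UMI) key, in any order."""
    pairs = [
        make_pair(r2=(1000 + p, 1050 + p), umi=u * 4, name=f"n{i}.{j}")
        for i, (p, j, u) in enumerate(entries)
    ]
    kept = b.deduplicate(pairs)
    assert len(kept) == len({dedup_key(p) for p in pairs})
    assert b.deduplicate(kept) == kept
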