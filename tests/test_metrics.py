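"""Quantification, pausing indices, ECDF/KS, size factors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import buttseq as b
from buttseq.core import GeneModel, GenomicInterval, SingleNtSignal
from buttseq.pause_detection import PauseSite

from conftest import ks_d_bruteforce


def _uniform_signal(chrom="c", strand="+", start=0, end=2000, per_base=1):
    sig = SingleNtSignal()
    for p in range(start, end):
        sig.add(chrom, strand, p, per_base)
    return sig


class TestQuantify:
    def test_half_open_boundary(self):
        sig = SingleNtSignal()
        sig.add("c", "+", 99)
        sig.add("c", "+", 100)
        region = GenomicInterval("c", 0, 100, "+")
        assert b.quantify(sig, [region]) == [1.0]

    def test_strand_matching_and_total(self):
        sig = SingleNtSignal()
        sig.add("c", "+", 10, 3)
        sig.add("c", "-", 10, 5)
        plus = GenomicInterval("c", 0, 100, "+")
        both = GenomicInterval("c", 0, 100, ".")
        assert b.quantify(sig, [plus, both]) == [3.0, 8.0]


class TestPausingIndex:
    def _gene(self, strand="+", length=3000):
        return GeneModel("g", "c", strand, [GenomicInterval("c", 0, length, strand)])

    def _pause(self, gene, offset):
        return PauseSite("g", "c", gene.strand, gene.offset_to_genomic(offset), 10, 1e-9, offset)

    def test_density_ratio_arithmetic(self):
        """100 reads over a 50-bp pause region vs 200 over a 1000-bp body."""
        gene = self._gene()
        pause = self._pause(gene, 49)  # pause region [0, 49] = 50 bp
        sig = SingleNtSignal()
        for p in range(50):
            sig.add("c", "+", p, 2)       # 100 reads
        for p in range(50, 1050):
            sig.add("c", "+", p, 0.2)     # 200 reads
        rec = b.pausing_index_anchored(gene, pause, sig)
        assert rec.pause_signal == 100 and rec.body_signal == pytest.approx(200)
        assert rec.index == pytest.approx(10.0)

    def test_uniform_signal_index_one(self):
        gene = self._gene()
        sig = _uniform_signal(end=3000)
        rec = b.pausing_index_anchored(gene, self._pause(gene, 80), sig)
        assert rec.index == pytest.approx(1.0)
        # gene at the contig start: the upstream 50 bp are clamped away, so
        # uniform signal gives a density-ratio index of exactly 1
        rec_f = b.pausing_index_fixed(gene, sig)
        assert rec_f.index == pytest.approx(1.0)

    def test_zero_body_flagged(self):
        gene = self._gene()
        sig = SingleNtSignal()
        sig.add("c", "+", 10, 50)
        rec = b.pausing_index_anchored(gene, self._pause(gene, 80), sig)
        assert rec.flagged and np.isnan(rec.index)

    def test_minus_strand_mirrored(self):
        gene = self._gene(strand="-")
        sig = SingleNtSignal()
        tss = gene.tss
        for p in range(tss - 49, tss + 1):
            sig.add("c", "-", p, 2)
        for p in range(tss - 1049, tss - 49):
            sig.add("c", "-", p, 0.2)
        rec = b.pausing_index_anchored(gene, self._pause(gene, 49), sig)
        assert rec.index == pytest.approx(10.0)

    def test_anchored_equals_fixed_in_constructed_case(self):
        """With the pause at +199 and the anchored body spanning the rest of
        the gene, both definitions see the same regions (given no signal
        upstream of the TSS)."""
        gene = self._gene(length=1200)
        sig = _uniform_signal(end=1200)
        anchored = b.pausing_index_anchored(
            gene, self._pause(gene, 199), sig, body_length=1000
        )
        fixed = b.pausing_index_fixed(gene, sig)
        # clamped fixed promoter [0, 200) == anchored pause region [0, 199]
        assert anchored.body_signal == fixed.body_signal
        assert anchored.index == pytest.approx(fixed.index)

    def test_body_truncated_at_tes(self):
        gene = self._gene(length=600)
        sig = _uniform_signal(end=600)
        rec = b.pausing_index_anchored(gene, self._pause(gene, 100), sig)
        assert rec.body_region.end == 600 and "truncated" in rec.flag_reason

    def test_invariant_to_library_scaling(self, small_sim, read_sim):
        _, ann, _, _ = small_sim
        pairs, _ = read_sim
        sig = b.build_signal(b.deduplicate(pairs))
        scaled = b.normalize_signal(sig, 2.5)
        for gene in ann.genes[:5]:
            pause = self._pause_for(gene)
            r1 = b.pausing_index_anchored(gene, pause, sig)
            r2 = b.pausing_index_anchored(gene, pause, scaled)
            if not r1.flagged:
                assert r1.index == pytest.approx(r2.index)

    @staticmethod
    def _pause_for(gene):
        return PauseSite(
            gene.gene_id, gene.chrom, gene.strand, gene.offset_to_genomic(60), 10, 1e-9, 60
        )


class TestEcdf:
    def test_step_values(self):
        f = b.Ecdf([1, 2, 3])
        assert f(2) == pytest.approx(2 / 3)
        assert f(0.5) == 0.0
        assert f(3) == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            b.Ecdf([])


class TestKs:
    def test_identical_samples_d_zero(self):
        r = b.ks_two_sample([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert r.D == 0.0 and r.p_value == 1.0

    def test_disjoint_supports_d_one(self):
        r = b.ks_two_sample([1, 2], [3, 4])
        assert r.D == 1.0

    def test_interleaved_half(self):
        assert b.ks_two_sample([1, 3], [2, 4]).D == pytest.approx(0.5)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=int(rng.integers(1, 50)))
        y = rng.normal(0.3, 1.2, size=int(rng.integers(1, 50)))
        assert b.ks_two_sample(x, y).D == pytest.approx(
            ks_d_bruteforce(x, y), abs=1e-12
        )

    def test_p_agrees_with_scipy_asymptotic(self):
        """Independent cross-check of the asymptotic p against scipy."""
        from scipy import stats

        rng = np.random.default_rng(5)
        x = rng.normal(size=400)
        y = rng.normal(0.25, 1, size=350)
        ours = b.ks_two_sample(x, y)
        ref = stats.ks_2samp(x, y, method="asymp")
        assert ours.D == pytest.approx(ref.statistic, abs=1e-12)
        assert np.log(ours.p_value) == pytest.approx(np.log(ref.pvalue), rel=0.2)


class TestSizeFactors:
    def test_identical_columns_unity(self):
        f = b.size_factors(np.array([[5, 5], [9, 9], [2, 2]]))
        assert np.allclose(f, 1.0)

    def test_hand_example(self):
        f = b.size_factors(np.array([[2, 4], [2, 4]]))
        assert f == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])

    def test_zero_feature_excluded_from_reference(self):
        with_zero = np.array([[2.0, 4.0], [2.0, 4.0], [0.0, 5.0]])
        assert b.size_factors(with_zero) == pytest.approx(
            [1 / np.sqrt(2), np.sqrt(2)]
        )

    def test_all_zero_rows_error(self):
        with pytest.raises(ValueError):
            b.size_factors(np.array([[0, 1], [1, 0]]))

    def test_recovers_known_scalings(self):
        rng = np.random.default_rng(7)
        base = rng.gamma(3, 50, size=1000)
        scalings = np.array([0.5, 1.0, 2.0, 1.3])
        counts = rng.poisson(np.outer(base, scalings))
        f = b.size_factors(counts)
        f = f / np.exp(np.mean(np.log(f)))
        want = scalings / np.exp(np.mean(np.log(scalings)))
        assert np.allclose(f, want, rtol=0.05)

    def test_matches_deseq2_reference_implementation(self):
        """Cross-check against pydeseq2's median-of-ratios on a random matrix."""
        from pydeseq2.preprocessing import deseq2_norm

        rng = np.random.default_rng(11)
        counts = rng.poisson(50, size=(200, 4)) + 1
        _, ref = deseq2_norm(counts.T)  # pydeseq2 is samples x features
        assert np.allclose(b.size_factors(counts), ref, rtol=1e-10)


class TestNormalizeSignal:
    def test_factor_one_identity_and_composition(self):
        sig = SingleNtSignal()
        sig.add("c", "+", 5, 8)
        assert b.normalize_signal(sig, 1.0) == sig
        ab = b.normalize_signal(b.normalize_signal(sig, 2.0), 3.0)
        assert ab == b.normalize_signal(sig, 6.0)
        assert ab.total() == pytest.approx(8 / 6)

    def test_nonpositive_factor_errors(self):
        with pytest.raises(ValueError):
            b.normalize_signal(SingleNtSignal(), 0.0)
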