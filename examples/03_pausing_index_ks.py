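"""Pause-anchored pausing indices and an ECDF/KS comparison of two conditions.

Condition B mimics pause-release inhibition: pause sites shifted 20 bp
upstream and pause strength doubled. The pipeline reports the median called
shift and a Kolmogorov-Smirnov comparison of the log2 pausing-index
distributions.
"""

import math

import numpy as np

import buttseq as b

cfg = b.SimConfig(
    n_genes=150, seed=21, pause_offset_range=(45, 140),
    gene_length_range=(3000, 6000), contaminant_fraction=0.0,
    rrna_fraction=0.0, pcr_duplication_rate=0.0,
)
ann, _, truth_a = b.simulate_genome(cfg)
truth_b = truth_a.with_pause_shift(-20, weight_factor=2.0)

sig = {}
for label, truth, seed in (("A", truth_a, 22), ("B", truth_b, 23)):
    pairs, _ = b.simulate_reads(truth, ann, 150 * 250, seed=seed)
    sig[label] = b.build_signal(b.deduplicate(pairs))

best = {
    label: b.top_pause_per_gene(b.detect_pauses(sig[label], ann.genes, seed=24))
    for label in sig
}
_, median_shift, _ = b.pause_shift(best["A"], best["B"])
print(f"median pause shift (B - A): {median_shift:+.0f} bp (planted: -20)")

gene_map = {g.gene_id: g for g in ann.genes}
log_idx = {}
for label in sig:
    vals = [
        math.log2(rec.index)
        for gid, site in best[label].items()
        if not (rec := b.pausing_index_anchored(gene_map[gid], site, sig[label])).flagged
    ]
    log_idx[label] = np.array(vals)
    print(f"condition {label}: median log2 pausing index = {np.median(vals):.2f}")

ks = b.ks_two_sample(log_idx["A"], log_idx["B"])
print(f"KS D = {ks.D:.3f}, p = {ks.p_value:.2e}")
# The inhibited condition's index ECDF sits to the right (higher pausing),
# and the KS test rejects equality decisively.
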