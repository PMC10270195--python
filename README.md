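# buttseq

Analysis toolkit for nascent-RNA 3′-end sequencing of promoter-proximal
RNA polymerase II pausing — from aligned read pairs to single-nucleotide
polymerase positions, bootstrap-called pause sites, pausing indices,
nucleosome-dyad relationships, and circadian time-course quantification.

## The problem

In 3′-end nascent-RNA libraries, the first base sequenced by read 2 is the
last base synthesized by an engaged RNA polymerase. Counting those bases at
single-nucleotide resolution yields a genome-wide map of polymerase
positions, dominated by a sharp peak 20–120 bp downstream of each TSS where
RNAPII pauses awaiting release (P-TEFb / superelongation-complex signaling).
This package implements the downstream analysis for such libraries:

* **Preprocessing** — UMI-exact deduplication of properly paired alignments
  (key: chromosome, read-2 strand, both mate 5′ positions, UMI), soft-clip
  bookkeeping, single-nucleotide 3′-end conversion, and strand-matched
  removal of small-RNA and exon-3′-end contaminant positions.
* **Pause detection** — for each candidate position with count
  *c* ≥ 5 within the first 200 transcribed bases, a bootstrap test against a
  uniform multinomial null in a 100-bp window: *T* window reads are dropped
  i.i.d. uniformly over the window's *W* positions and the resample maximum
  compared with *c*; *p* = (1 + *k*)/(*n*<sub>boot</sub> + 1) with an exact
  binomial tail bound min(1, *W*·P(Bin(*T*, 1/*W*) ≥ *c*)) replacing the
  bootstrap floor when *k* = 0. One pause per gene (highest count,
  ties toward the TSS).
* **Pausing index** — density ratio of the pause region [TSS, pause] to the
  1000 bp downstream of the pause (or a fixed −50/+200 promoter window),
  compared across conditions with ECDFs and an exact two-sample KS *D*.
* **Normalization** — median-of-ratios size factors over regions of
  interest (library depth is meaningless when contaminant content differs).
* **Metagene profiles** — TSS-anchored or scaled matrices at 1-bp bins,
  0.1% outlier trimming, log2(x+1), 10,000-rep percentile-bootstrap 95% CI.
* **Chromatin** — 58 ± 5 bp subnucleosomal MNase fragments, dyad-half
  pairing into nucleosome centers, −1 (TSS-overlapping) nucleosome calls,
  and pause clustering by distance (bins 80–120 / 60–79 / 40–59 / 20–39 /
  0–19 bp downstream of the center).
* **Comparative** — two-condition pause/body 3×3 concordance grid and
  exon-only circadian time-course quantification with peak normalization.
* **Synthetic data** — a ground-truthed generator (genome, UMI-tagged read
  pairs with PCR duplicates and contaminants, MNase dyads, sinusoidal time
  courses, two-tissue class plantings) against which every stage is tested.

## Worked example

```python
import buttseq as b

cfg = b.SimConfig(n_genes=100, seed=11, contaminant_fraction=0.0, rrna_fraction=0.0)
ann, genome, truth = b.simulate_genome(cfg)
pairs, rst = b.simulate_reads(truth, ann, 30_000, seed=12)
signal = b.build_signal(b.deduplicate(pairs))

sites = b.detect_pauses(signal, ann.genes, b.PdaParams(), seed=13)
best = b.top_pause_per_gene(sites)
pfm = b.extract_pause_motif(best.values(), genome)
```

Running this (`python examples/02_call_pause_sites.py`) prints

```
sites called: 100 in 100 genes
exact-base recovery of true pause sites: 100/100
base at -1: G   base at +1: T
```

i.e. every simulated gene's pause site is recovered at the exact base, and
the G(−1)/T(+1) pausing dinucleotide planted by the generator is recovered
by the strand-corrected position-frequency matrix. The other scripts in
`examples/` walk through preprocessing/QC, the pause-shift + KS analysis of
a pause-release-inhibited condition, metagene profiles, nucleosome-dyad
clustering, the two-tissue concordance grid, and the circadian time course
(including the constitutive-pause gene class whose pause stays flat while
the gene body cycles ~20-fold).

A thin CLI mirrors the library:
`buttseq {simulate,preprocess,callpauses,index,metagene,nucdist,compare,circadian,demo}`;
`buttseq demo --out-dir OUT --seed N` runs the whole pipeline on synthetic
data, bit-reproducibly per seed.

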