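# Methods

This note documents the models and procedures implemented in `tfbskit`, the
defaults and why they were chosen, the numerical choices, what the synthetic
fixtures do and do not emulate, and known limitations.

## Regulatory-region model

Regions are anchored at the translation initiation codon (TIC) and the
translation stop codon (TSC) rather than transcription start/end sites:
start/stop codons are annotated consistently even in genomes without
full-length transcript evidence, and some genes lack annotated 5′ UTRs. A
consequence is that 5′-UTR sequence between the TSS and the TIC is *not*
part of the upstream window.

Construction rules:

1. The full structure is `upstream_len` bp before the TIC (allowed 1000,
   3000, 5000), the representative isoform's introns (optional), and
   `downstream_len` bp after the TSC (0 or 1000).
2. If a neighboring gene body overlaps an upstream/downstream window, the
   window is cut at the neighbor's boundary, keeping the gene-proximal
   intergenic part. "Neighboring gene" means any gene on either strand.
3. If the gene body itself overlaps another gene on the *opposite* strand,
   full standard windows are kept (no trimming). The flag
   `strand_exception=False` disables this exemption.
4. The representative isoform is the one with the largest spliced exon
   length; equal lengths break ties by lexicographically smallest transcript
   ID, which makes selection deterministic.
5. Introns longer than `intron_max_len` (default 5000 bp) are skipped, as
   very long annotated introns are often annotation artifacts and dominate
   scan time.

Degenerate cases: a gene wholly contained in a same-strand gene gets
zero-length windows (with a warning); windows are truncated at contig
edges; a malformed interval (end < start) is a hard error naming the gene.

Coordinates are 0-based half-open internally; GFF3 input is converted from
1-based inclusive, BED output is 0-based half-open. Minus-strand regions are
reverse-complemented and stitched in gene orientation (upstream, introns
5′→3′, downstream); every position carries a signed TIC-relative offset with
−1 for the base immediately 5′ of the TIC.

## PWM scanning

PWMs are W×4 column-stochastic matrices. Scanning uses the log2-odds
transform against an order-0 (mononucleotide) background estimated from the
scanned region set and recomputed per genome and region setting. The
pseudocount is distributed proportionally to the background,
p′ = (p + ε·q)/(1 + ε), so a uniform column scores 0 against a uniform
background for any ε.

**fimo mode.** Every window is scored on both strands; the null
distribution of the score is computed exactly by column-wise convolution of
the per-position score distributions after discretizing scores to 1000 bins
over the motif's score range (a standard precision/speed trade-off; the
discretization error of a window score is bounded by W·range/1000). The
scanner scores windows with the same discretized integers, so scan-time
p-values agree exactly with the DP table. A window is a hit when its
best-strand p-value is ≤ 10⁻ˢ; with `max_strand` (default) only the better
strand is reported per position, ties going to the plus strand. The score
threshold s is interpreted as −log10 of the nominal per-window match
p-value. The same tail table is applied to both strands. The fimo-mode
pseudocount default is 0.1; an exact-p-value request with pseudocount 0 is
an error (−∞ scores).

**cluster mode.** Candidate matches are windows whose best-strand log-odds
score is ≥ m (default 5, pseudocount 0, so impossible bases score −∞ and
can never reach m). Candidates are chained by a linear dynamic program over
non-overlapping matches in which linking two matches d bp apart costs d/g
bits (g = 35 bp, the expected within-cluster gap of the original
dense-cluster tool). Disjoint maximal chains with total score ≥ c (default
5) are reported as clusters, extracted greedily in descending chain score;
every member match becomes a hit attributed to its PWM and carrying the
cluster score. This is a faithful re-derivation of the dense-cluster
objective (match scores minus spacing penalties), not a bit-exact clone of
any external binary. A gene counts as "hit" by a motif only when that motif
matches inside a reported cluster.

Windows containing N are skipped in both modes. Hits are reported with
TIC-relative offsets and deterministic sort order (gene, offset, motif).

## Enrichment statistics

With M genes in the genome, N carrying ≥ 1 hit of a motif, and x of the n
query genes carrying a hit:

* P = P(X ≥ x) for X ~ Hypergeom(M, N, n) — the upper tail, which is the
  quantity an enrichment question needs; the single probability mass at x is
  available as `mode="pmf"`.
* FDR — Benjamini–Hochberg across all motifs tested in one query run (one
  family of hypotheses per run).
* FE = log2((x/n)/(N/M)). Motifs with x = 0 cannot be enriched and are
  omitted from the table (their count is reported in the run metadata).
* S-Score = (−log10 P) × FE, with P floored at 1e-300 against underflow.
  Depleted motifs (FE < 0) get negative S-Scores and rank last.

Tables sort by S-Score descending, ties broken by P ascending then motif ID,
making the ordering bit-reproducible. Query IDs absent from the genome are
dropped with a logged count; duplicates collapse.

## Threshold calibration

The top S-Score of a query is an extreme-value statistic across all motifs,
so its null distribution is estimated empirically: `n_sets` (default 10 000)
uniform random gene sets of `set_size` (default 500) are drawn without
replacement within a set and independently across sets, each is run through
the same vectorized statistics as the enrichment engine, and the 95th/99th
percentiles (linear interpolation between order statistics) of the top
S-Scores become the 5%/1% thresholds. The seed is recorded in the output. A
draw in which no motif fires at all contributes the sentinel 0. Backgrounds
are uniform random gene sets, not GC- or length-matched.

The test suite and the acceptance script use 1000 background sets instead of
10 000, with correspondingly widened coverage tolerances (±0.02 at the 5%
level, ±0.01 at 1%); the percentile estimate at 1000 draws is accurate to
roughly ±0.7% / ±0.3% absolute at the two levels.

## Benchmark harness

Target lists are built from gene-relative peak tables: a gene qualifies when
a peak overlaps [−3000 bp relative to the TSS, TES + 1000 bp], and the top
500 genes by ascending adjusted q-value are kept. Positive queries subsample
bound genes (sizes 50/100/250/500, 10 replicates); negative queries sample
non-bound genes to the same size.

The normalized rank of the expected motif is r = (best rank − 1)/(table
length − 1), with ties sharing the mean rank and an absent motif scoring the
defined worst case r = 1. When several PWMs represent the expected TF, the
best rank counts. ROC curves sweep a threshold t declaring r ≤ t "detected";
the trapezoid AUC equals the normalized Mann–Whitney U of negative-vs-
positive ranks (ties credited 1/2), which the tests verify to 1e-9. Both
sort keys (S-Score and FDR) are evaluated from the same enrichment tables
without re-scanning.

## Orthology

Proteomes are translated from the representative CDS (standard code, phase
of the 5′-most CDS segment honoured, trailing stop stripped); internal stops
exclude the gene with a warning, and a CDS length not divisible by 3 is
truncated to the codon boundary. BRH consumes BLASTP outfmt-6 tables; the
best hit per query is highest bitscore, ties broken by lowest E-value then
lexicographic subject (bitscore first because E-values commonly tie at 0).
Pairs are kept iff mutually best with both E-values ≤ 1e-10. For
self-contained tests a pairwise aligner (BLOSUM62, affine gaps −11/−1,
Karlin–Altschul E-values with gapped parameters λ = 0.267, K = 0.041) stands
behind the same table format; it is intended for fixture proteomes of tens
of sequences, not as a general aligner.

## Synthetic fixtures

The generator emulates the pipeline's external inputs at desk scale: a
single-chromosome genome with i.i.d. background sequence at configurable GC
content (40% default, typical of plant euchromatin), ~2000 genes with 1–3
isoforms, valid ORFs, and the annotation corner cases the region rules must
handle (contig-edge gene, tight same-strand neighbors at 500 bp, an
opposite-strand overlapping pair, a 6-kb intron). A consensus motif is
planted in the 1-kb upstream window of 80% of a 100-gene target set and 5%
of background genes — rates chosen so recovery is unambiguous while the
background still produces chance hits. Planted PWMs are sharp (consensus
probability 0.97 per position) so scanner recovery is deterministic and
separable from the statistics; a soft tier (0.7) exercises the p-value
machinery. Mean intergenic spacing is 3 kb (Arabidopsis-like gene density),
minimum 1.5 kb so 1-kb windows of ordinary genes are intact.

What the fixtures do **not** emulate: repeats and low-complexity sequence,
isochore structure, realistic motif co-occurrence, UTR annotation beyond the
overlap pair, and the scale of real genomes (10⁴–10⁵ genes, 1500+ PWMs).
Passing tests therefore demonstrate correctness of the algorithms and
statistics under the stated generative model, not performance
characteristics on real annotation pathologies.

## Numerical and design choices

* Hypergeometric tails come from `scipy.stats.hypergeom.sf` (log-space,
  stable for M up to 10⁵); the test suite verifies agreement with exact
  enumeration to 1e-12 for all configurations with M ≤ 30.
* The calibration resampler and the enrichment engine share one vectorized
  statistics routine so thresholds and table scores can never diverge.
* Overlapping candidate matches within a cluster are resolved by the chain
  DP itself, which selects the highest-scoring compatible subset;
  equal-score links resolve to the earlier candidate.
* M (the genome gene count) counts protein-coding genes with buildable
  regions, not all annotated genes.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; pipeline re-runs are byte-identical except timestamps.
* Problem sizes in the acceptance script (2000-gene genomes, 1000
  calibration sets, 20 benchmark cases, 50-protein proteomes) are the
  package's desk-scale study conditions; they keep a full from-scratch run
  under a minute while leaving every statistic well-resolved.

## Known limitations

* The scanners are re-derivations, not bit-exact clones of external FIMO /
  Cluster-Buster binaries; q-values are not computed inside the scanner
  (FDR lives in the enrichment engine).
* Order-0 backgrounds only; no dinucleotide or higher-order models.
* The cluster-mode gap penalty is linear in spacing; the original tool's
  probabilistic gap model is approximated, so cluster boundaries can differ
  in edge cases even though the dense-vs-sparse behaviour matches.
* BRH orthology ignores synteny/collinearity and orthogroup structure.
* Uniform random calibration backgrounds do not correct for GC or region-
  length biases of a particular query.
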