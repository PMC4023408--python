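# Methods

`motifassoc` asks a single scientific question in several coordinated
ways: does the loss of a transcription factor (TF) change the expression
of the genes whose promoters carry that factor's binding motif — and do
two factors with similar knockout phenotypes act on a shared target set?
This note documents the statistical machinery, the defaults and why they
were chosen, the synthetic data the package tests itself against, and
the known limitations.

## The Motif Association Score

For a motif `M` (an L×4 position frequency matrix) and one knockout
study, every gene's proximal promoter — the ±1000 bp window around its
TSS, using the TSS of the shortest annotated transcript — is scanned on
both strands with the log2-odds form of `M`, and the single best window
score is kept per promoter. Genes are partitioned by the knockout
expression data into

* **activated** (KO/WT ≤ 0.5 and q ≤ 0.05: the factor apparently
  sustains their expression),
* **repressed** (KO/WT ≥ 2 and q ≤ 0.05), and
* **non-target** (everything else with expression data).

Both fold-change thresholds are inclusive ("at least 2-fold"). Two
one-sided Wilcoxon rank-sum tests compare best promoter scores of the
activated (resp. repressed) genes against the non-target genes, giving
`p_act` and `p_rep` under the null that the scores are no better in the
target set. The two are combined into the signed score

    MAS = -log10(min(p_act, p_rep)),  sign + iff p_act <= p_rep.

MAS is a *ranking* score: neither p-value is adjusted for the number of
motifs tested, so results carry the motif count and users who need
calibrated significance should correct across it. For a two-knockout
analysis the same computation runs on the intersected partition: common
activated = activated_A ∩ activated_B, and the common non-target set is
the intersection of the two non-target sets, all restricted to genes
measured in both studies.

Rank-sum details: the exact null distribution is used when the pooled
sample has ≤ 20 observations and no ties; otherwise the normal
approximation with tie correction and a 0.5 continuity correction.
p-values are clamped to [1e-300, 1] so an approximation underflow can
never produce an infinite MAS. Fully tied samples (e.g. a motif that
matches nothing anywhere, leaving every gene at the sentinel score)
return p = 0.5 and are flagged.

## Promoter scanning and exact score p-values

Scores are log2-odds against a 0-order background:
`score[i][b] = log2((counts[i][b] + pc·bg[b]) / (rowsum_i + pc) / bg[b])`.
Defaults: pseudocount 0.1 distributed proportionally to the background
(a common scanning convention), and background estimated from the
scanned sequence set itself, with a uniform option. Windows containing
an ambiguous base (N) — or a soft-masked base when masking is enabled —
are skipped; a promoter with no scorable window receives a *sentinel*
score one granularity step below the motif's minimum achievable score,
so such genes rank strictly last in the rank-sum tests rather than
silently disappearing (a flag drops them instead).

Per-window score p-values are computed exactly by dynamic programming:
position scores are discretized to bins of 1/1000 bit and convolved
across positions under the background, yielding P(score ≥ s) for a
random background word. The bin width was chosen so that tail
probabilities near 1e-5 — the site-calling threshold used for the peak
quality check — are stable to well under 5% relative error; the test
suite verifies exact agreement with exhaustive 4^L enumeration for
motifs up to length 6 and cross-checks the default granularity against
a 10× finer one. Words that hit a -inf entry (possible only at
pseudocount 0) keep their probability mass strictly below every finite
score bin.

## Peak geometry and the shuffle control

Peak summits are assigned to the nearest TSS on their chromosome with a
signed distance (negative = gene-upstream; the sign flips for minus-
strand genes). The distance distribution is visualized as a Gaussian
kernel density with fixed bandwidth h = 0.4 on the transformed axis
x = sign(d)·log10(1 + |d|). The transform is a deliberate reading of an
ambiguous convention: a bandwidth of 0.4 is implausible in linear base
pairs on an axis spanning five decades, but natural in log10 units; a
linear mode is selectable. The null model repositions each summit
uniformly on its own chromosome (seeded).

Motif enrichment in peaks uses 100 bp windows centered on summits: at
each score p-value threshold, the fraction of windows with at least one
site on either strand is compared against the same scan of one
k-let-preserving shuffle per window (k = 3, preserving trinucleotide
frequencies; n-shuffle averaging is available). The shuffle is the exact
Eulerian-path method on the de Bruijn multigraph of (k-1)-mers — a
uniform random in-bound arborescence (rejection-sampled last-edge
choices) followed by uniform permutation of remaining out-edges — which
by the BEST theorem draws uniformly from all sequences with exactly the
input's k-mer multiset. Naive swapping heuristics are neither exact nor
uniform; exact multiset preservation is asserted for k ∈ {1..4}. The
ENCODE-style quality criterion passes when ≥ 10% of peaks contain the
motif at ≥ 4-fold enrichment over the control at the 1e-5 threshold.

The proximity table counts, per gene set and radius (1/10/100 kb),
genes with at least one summit within the radius of their selected TSS,
with a two-tailed Fisher exact test of each set against all other genes
in the expression universe ({in set, not in set} × {peak ≤ r, none}).
Peaks equidistant from two TSSs go to the lower-coordinate TSS; this
affects labels only, never distances.

## Knockout target overlap

For target sets A and B from two knockouts in a shared universe C (the
genes with expression data in *both* studies — the expected overlap and
fold depend directly on |C|, so it is logged and carried in results),
the overlap z = |A∩B| is hypergeometric under independence; the package
reports P(Z ≥ z), the expectation m·k/(n+m) with m=|A|, k=|B|,
n=|C|−|A|, and the fold z/expectation. Tails are computed through
log-gamma binomial coefficients (scipy), verified against exact
rational pmf summation for all |C| ≤ 60. Shared targets additionally
get sign-concordance counts and the Pearson correlation of their paired
log2 fold changes (pairs with an exactly zero value are excluded from
sign counts and reported).

## Differential expression

The primary ingestion path is a per-probe table (probe, gene, log2fc =
log2(KO/WT), p) from any upstream fit. Probes collapse to the most
significant one per gene (ties: larger |log2fc|, then probe id);
q-values are Benjamini–Hochberg step-up, verified against a brute-force
implementation of the definition.

For synthetic replicate matrices the package provides a two-group test
with two variance modes. `per_probe` is the classic pooled-variance
t-test within each probe. `common` estimates one residual variance
shared by all probes (the mean within-group variance across the matrix)
and refers the statistic to the normal distribution. The common mode is
the default for the synthetic pipeline and the right model for it: the
generator draws replicate noise i.i.d. with a single σ across all
probes, so the shared-variance estimator is exact there, whereas a
3-vs-3 per-probe t-test has only 4 degrees of freedom and essentially
no power after FDR control at 10^4 genes — real array analyses solve
the same problem by moderating variances across probes. Real studies
should supply the output of a proper array/RNA-seq model instead of
using either mode.

The GO-ranking key orders genes by the *maximum* of the two knockouts'
fold changes on the ratio scale, ascending, so genes strongly down in
both studies lead the list.

## The synthetic study generator

`SyntheticConfig` defaults define the study conditions used by the test
suite:

| parameter | default | meaning |
|---|---|---|
| n_genes / n_chroms / chrom_length | 10,000 / 4 / 6.5 Mb | i.i.d. uniform-composition genome, evenly spaced genes, both strands |
| flank | 1000 bp | promoter half-width |
| motif | 13 bp TGGC-N5-GCCA palindrome | half-sites at 0.95, spacer at 0.45 |
| plant_prob_activated / background | 0.4 / 0.05 | per-promoter planting probability |
| n_peaks / peak_jitter_sd | 759 / 20 bp | one summit per planted site + uniform background peaks |
| n_targets_a / n_targets_b / n_overlap | 300 / 300 / 60 | designed knockout target sets |
| effect mean / sd | 1.5 / 0.5 (log2) | knockout down-regulation magnitude |
| overlap_effect_weight | 0.7 | shared-draw weight for overlap genes' effects |
| noise_sd / n_reps | 0.4 / 3 | replicate noise and replicates per group |

Planted sites are fresh draws from the motif's probability matrix
written at a uniform offset in the promoter window on a random strand.
The spacer positions of the planted motif carry weak preferences
(0.45) rather than being uniform: with 5 fully uniform columns the
per-window score distribution would be so coarse that no site could
reach a p-value below 4^-8 ≈ 1.5e-5, making the 1e-5 site-calling
threshold unsatisfiable by construction; SELEX-derived dimer motifs do
show such weak spacer preferences. Overlap genes draw their effect as
0.7·shared + 0.3·own, producing correlated fold changes between the two
knockouts as expected of a co-regulated set. Decoy motifs for recovery
benchmarks are column permutations of the planted motif: identical
information content and composition, destroyed sequence match.

What the generator does *not* emulate: chromatin state, mappability,
repeat structure, GC-heterogeneous backgrounds, probe-specific array
noise, or indirect regulatory cascades. Passing recovery tests
therefore show that the statistics detect the designed signal at
realistic sizes and noise — not that the pipeline is robust to every
artifact of real ChIP-seq or arrays.

Everything is reproducible bit-for-bit from (config, seed); all
randomness descends from the single seed.

## Problem sizes in the self-checks

The end-to-end recovery checks run the full pipeline at the default
scale above over 10 seeds (planted motif vs 20 decoys; recovered-set
overlap; ENCODE check on the simulated peaks) and a null calibration
(planting at background rate everywhere, no designed overlap, 150 decoy
motifs) in which the activated-side p-values are uniform by KS test.
Unit-level oracles run at exhaustively enumerable sizes: motifs ≤ 6 bp
against 4^L enumeration, rank-sum samples of 8+8 against all C(16,8)
permutations, hypergeometric universes ≤ 60 genes against rational
arithmetic, shuffle uniformity against full Eulerian-walk enumeration
of a 12 bp instance.

## Known limitations

* Promoter windows are fixed-width and symmetric; regulatory input from
  distal elements is invisible to MAS by design.
* The rank-sum normal approximation is used for all compendium-scale
  scans; its error against the exact permutation distribution is ≤ 0.01
  at n = 8+8 and shrinks with sample size, but extremely small target
  sets (< 5 genes) give unstable p-values, which the results flag.
* The hypergeometric overlap model assumes target sets are drawn
  independently given the universe; shared detection biases (e.g. both
  studies under-powering low-expression genes) inflate the apparent
  enrichment and are not modeled.
* `upgma_cluster` assumes the motif-distance matrix is a dissimilarity
  (e.g. 1 − Pearson similarity); UPGMA trees are ultrametric by
  construction and distort non-ultrametric distances.
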