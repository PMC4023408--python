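# motifassoc

Links three kinds of evidence about a transcription factor (TF) in one
analysis: **where it binds** (ChIP-seq peak summits), **which genes
respond to its loss** (knockout vs wild-type differential expression),
and **whether its DNA-binding motif is enriched in the promoters of the
responding genes**. It is written for regulatory genomicists who have a
peak list, one or two knockout expression tables, and a motif
compendium, and want a ranked, statistically grounded answer to "which
motifs explain these expression changes — and do these two factors
co-regulate a common target set?"

## The statistic at the core

For a motif *M*, every gene's proximal promoter (±1000 bp around the
TSS of its shortest transcript) is scanned on both strands with the
log2-odds form of *M* and the best window score is kept. Genes are
partitioned by the knockout data into *activated* (KO/WT ≤ 0.5,
q ≤ 0.05), *repressed* (KO/WT ≥ 2, q ≤ 0.05) and *non-target* sets.
One-sided Wilcoxon rank-sum tests give

> p_act = P(promoter scores of activated genes are no better than
> non-targets), and p_rep likewise for repressed genes,

combined into the signed **Motif Association Score**

> MAS = −log10(min(p_act, p_rep)), positive iff p_act ≤ p_rep.

A large positive MAS marks a motif whose presence predicts loss of
expression in the knockout — the signature of direct activation. The
p-values are deliberately unadjusted (MAS ranks motifs; correct across
the motif count yourself if you need calibrated significance).

Around the core score the package provides: exact per-window score
p-values by dynamic programming (so sites can be called at a threshold
like 1e-5); k-let-preserving Eulerian shuffles (k = 3 conserves
trinucleotide counts exactly) as the control for peak motif enrichment
and the ENCODE-style quality check; peak-to-TSS signed distance
profiles with a uniform repositioning null and fixed-bandwidth KDE;
hypergeometric overlap statistics between two knockouts' target sets
with fold-change concordance; motif Pearson similarity with UPGMA
clustering to newick; and a fully seeded synthetic-study generator with
planted ground truth. See `docs/methods.md` for the details and
defaults.

## Worked example

Simulate a two-knockout study with planted structure, classify targets,
test the overlap, and rank the planted motif against 20 shuffled-column
decoys:

```python
from motifassoc import (SyntheticConfig, simulate_study,
                        hypergeom_overlap, MotifAssociation)
from motifassoc.expression import (two_group_diff, collapse_probes,
                                   bh_adjust, classify_targets)
from motifassoc.simulate import decoy_motifs

config = SyntheticConfig(seed=42, n_genes=2000, n_chroms=2,
                         chrom_length=2_500_000, n_targets_a=120,
                         n_targets_b=120, n_overlap=30, n_peaks=300)
study = simulate_study(config)

def classify(ko, label):
    probes = two_group_diff(ko["matrix"], ko["groups"],
                            ko["probe_genes"], variance="common")
    genes = collapse_probes(probes)
    genes["q"] = bh_adjust(genes["p"].to_numpy())
    return classify_targets(genes, ko_label=label)

cls_a, cls_b = classify(study.study_a, "KO_A"), classify(study.study_b, "KO_B")
universe = cls_a.universe & cls_b.universe
print(hypergeom_overlap(cls_a.activated & universe,
                        cls_b.activated & universe,
                        universe, label="activated").summary())

motifs = [study.motif] + decoy_motifs(study.motif, 20, seed=1)
results = MotifAssociation.from_promoters(motifs, study.promoter_set(),
                                          cls_a).fit()
print(results.summary())
```

This prints:

```
Overlap activated: |A|=108, |B|=111, |C|=2000
  observed overlap  28
  expected overlap  6.0
  fold enrichment   4.7
  P(Z >= z)         4.17e-13

Motif Association Score results
================================================================
motifs tested: 21   (p-values unadjusted; apply your own multiple-testing correction across this count)
gene sets: activated=108, repressed=6, non-target=1886
----------------------------------------------------------------
 rank    motif_id gene_label     p_act   p_rep     mas
    1 PLANTED_NFI       Nfib 0.0008632  0.3906   3.064
    2   DECOY_017       None   0.06303  0.8336     1.2
    3   DECOY_016       None    0.1595  0.9821  0.7972
...
```

Reading it: of the 120 designed targets per knockout, 108 and 111 are
recovered at the 2-fold / q ≤ 0.05 thresholds; their activated sets
share 28 genes where 6.0 would be expected by chance (4.7-fold,
p ≈ 4e-13) — the designed co-regulation. The planted motif tops the MAS
ranking (p_act ≈ 9e-4, MAS ≈ +3.1) while every column-permuted decoy
stays near 0, i.e. promoter motif content in the recovered activated
set points back at the planted factor.

The same analysis runs from the shell on files
(FASTA/BED/TSV/MEME-format motifs):

```bash
motifassoc simulate --seed 42 --out study/
motifassoc scan --genome study/genome.fa --tss study/tss.bed \
                --motifs study/motifs_with_decoys.meme --out run/
motifassoc mas --scores run/promoter_scores.tsv \
               --expression-a study/expression_a.tsv --out run/
motifassoc overlap --expression-a study/expression_a.tsv \
                   --expression-b study/expression_b.tsv --out run/
motifassoc peaks --peaks study/peaks.bed --tss study/tss.bed \
                 --genome study/genome.fa --chrom-sizes study/chrom.sizes \
                 --motifs study/planted_motif.meme --out run/
```

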