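# mirderep

Analysis toolkit for quantifying **miRNA target derepression** in bulk
RNA-seq, built around the question: when a miRNA is lost (or a single target
is made resistant to it), how much do the miRNA's predicted targets rise,
and is the change transcriptional or post-transcriptional?

It is written for transcriptomics analysts working on miRNA regulatory
circuits — e.g. the miR-200a/b–ZEB1 double-negative feedback loop in the
mouse pituitary — who need the full chain from raw small-RNA reads and count
tables to a defensible, length-confound-free target-set statistic.

## What it computes

**The core statistic.** For a miRNA family with predicted target set *T*
(from context++-style prediction tables), the expression-filtered gene
universe is split into 10 equal-count bins by 3′-UTR length. For each target,
one non-target is drawn with replacement from the same length bin, giving a
matched cohort *C* with the identical UTR-length histogram. The report for
each target set (all / conserved / top 10% by cumulative weighted context++
score) is

&nbsp;&nbsp;Δ = median log₂FC(*T*) − median log₂FC(*C*)  (derepression orientation),

with a Mann–Whitney test between the two fold-change samples. The draw is
repeated 21 times; the mean Δ and the median *P* across replicates are
reported. Length matching matters because predicted targets have
systematically longer 3′ UTRs, and UTR length itself covaries with
expression changes — an unmatched control pool produces a biased Δ.

**Around it:**

- `diffexpr` — two-group negative-binomial differential expression:
  median-of-ratios size factors, moment dispersion with trend shrinkage,
  per-gene NB GLM Wald test (log₂FC, SE, STAT = log₂FC/SE), BH adjustment,
  and the standard display filters (control CPM > 1, |log₂FC| ≤ 5, mean raw
  counts ≥ 50).
- `smallrna` — mature-miRNA quantification from FASTQ: Q30 filter, 3′-adapter
  trimming with 4-nt randomized ligation flanks, exact 18/19-nt prefix
  dictionary matching with collision detection, spike-in removal, CPM.
- `intervals` — per-gene exon unions and merged-intron annotations from GTF,
  plus a union-mode read counter (strandedness 0/1/2) for validating
  exon/intron pipelines.
- `concordance` — exon-vs-intron fold-change concordance (transcriptional
  changes move pre-mRNA and mRNA together; post-transcriptional ones move
  only exons), cross-genotype fold-change regression, Welch gene-set shift
  tests, Fisher set overlap, variable-gene PCA.
- `simulate` — a synthetic-data generator that plants the whole effect
  structure (transcriptional repression on exons *and* introns,
  post-transcriptional derepression on exons only, UTR-length bias on
  targets, miRNA abundance collapse, adapters/flank/spike-in read structure)
  so every stage is testable end to end without downloads.

## Worked example

Simulate a study-scale dataset (2000 genes, control/het/hom genotypes, a
planted ~1.19× derepression on miR-200b/c/429 targets), run differential
expression hom vs control, then the matched target-set analysis:

```bash
mirderep simulate --seed 11 --out-prefix demo/sim --n-reads 50000
mirderep de --counts demo/sim.exon_counts.tsv --meta demo/sim.samples.tsv \
            --control control --test hom --out demo/sim.de.tsv
mirderep target-analysis --de demo/sim.de.tsv \
    --predictions demo/sim.predictions.tsv --utrs demo/sim.utr_lengths.tsv \
    --family "miR-200b/c/429" --exclude-families "miR-200a/141" \
    --reps 21 --seed 11 --out-prefix demo/sim.targets
```

which prints

```
2000 genes tested, 261 with padj < 0.05
{
  "all":       {"n": 57, "mean_derepression": 0.354, "median_p": 1.4e-11},
  "conserved": {"n": 18, "mean_derepression": 0.372, "median_p": 9.1e-06},
  "top":       {"n": 6,  "mean_derepression": 0.385, "median_p": 0.0087}
}
```

Read: of the genes passing the ≥50-raw-count filter, 57 are predicted
miR-200b/c/429 targets; their median log₂ fold change sits ~0.35 above that
of UTR-length-matched non-targets (the generator planted log₂(1.25) ≈ 0.32 on
this family's targets), the shift is highly significant, and it persists in
the conserved and top-score subsets. Per-set ECDF curves and the full
replicate table are written as TSV next to the summary.

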