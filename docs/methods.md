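# Methods

## The matched-resampling derepression statistic

For a miRNA family *f* with prediction table records (gene, family,
cumulative weighted context++ score, conserved flag), three nested target
sets are formed within the analysis universe: **all** predicted targets,
the **conserved** subset, and the **top** fraction (default 10%, ranked by
most negative cumulative score; size ⌈0.10·n⌉, score ties broken by gene
id). The universe is every gene with (i) a finite log₂ fold change, (ii)
average raw counts ≥ 50 across the samples of the comparison, and (iii) a
known 3′-UTR length.

The universe is partitioned into 10 equal-count UTR-length bins (quantile
bins; ties broken by stable gene-id order so assignment is
order-invariant). Quantile bins are used rather than equal-width bins
because UTR lengths are roughly log-normal and equal-width bins would leave
upper bins nearly empty, making matched draws degenerate. For each target,
one gene is drawn uniformly **with replacement** from the same bin of the
nontarget pool — the universe minus all predicted targets of the focal
family and of any excluded families (for miR-200-centred analyses, miR-200
family targets are excluded when scoring other families, and the exclusion
applies to the whole predicted-target list, not only the subset being
scored). The same nontarget may serve several targets within one replicate;
the cohort's bin histogram equals the target set's by construction.

Per replicate the statistic is the difference of median log₂ fold changes,
carried in both orientations with unambiguous names: `derepression` =
median(target) − median(nontarget) and `repression` = its negation. A
two-sided Mann–Whitney test (midranks; exact by enumeration when
n_x·n_y ≤ 400 and tie-free, else normal approximation with tie and
continuity corrections) compares the two fold-change samples. The draw is
repeated 21 times (odd, so the median *P* is an order statistic); the
report contains per-replicate arrays, the mean Δ, the median *P*, and ECDF
curves for the three target sets plus the all-set cohort from the median-*P*
replicate. Replicate *r* uses the seed sequence `[seed, r]`, so any single
replicate is reproducible in isolation. Two-sided testing is the default
(direction is a finding, not an assumption); a one-sided alternative is a
parameter.

`matched=False` replaces the binned draw with a uniform draw from the whole
pool. This is not an analysis mode but the control demonstrating the
method's purpose: under a fold-change gradient in UTR length with no true
target effect, the matched statistic stays unbiased while the unmatched one
inherits the length bias (both are measured by the validation suite).

Family selection for a systematic screen (`select_families`) requires a
differentially expressed member (padj < 0.05), family abundance
(summed member control CPM ≥ 1000, inclusive), and ≥ 100 conserved predicted
targets (inclusive) after exclusion-list removal. Family abundance and DE
status are aggregated over member miRNAs because mature members of one
family share the target repertoire being scored.

## The negative-binomial engine

A deliberately lightweight two-group engine, not a re-implementation of the
reference tools:

- **Size factors**: median-of-ratios over genes with nonzero counts in all
  samples; errors with guidance when no such gene exists.
- **Dispersion**: per-gene method of moments on normalized counts pooled
  within groups, `α = (s² − μ·mean(1/sf))/μ²`, floored at 1e-8, then blended
  50/50 with an OLS-fitted trend `α(μ) = a₀ + a₁/μ`. There is no
  empirical-Bayes shrinkage across genes beyond this blend, no Cook's
  outlier handling, and no independent filtering.
- **Wald test**: per-gene NB GLM with log link, per-sample log size-factor
  offset and a group indicator, fit by IRLS vectorized across genes
  (working weights μ/(1+αμ); convergence at relative coefficient change
  < 1e-8 or 100 iterations; linear predictors clipped at ±30). log₂FC is
  the raw coefficient over ln 2 (no fold-change shrinkage); SE comes from
  the observed information; *p* is two-sided normal on STAT = log₂FC/SE;
  BH adjustment over testable genes with NA propagated and excluded from m.
- **Degenerate genes**: all-zero genes get NA throughout; genes with zero
  counts in exactly one group get a signed infinite log₂FC sentinel and NA
  statistics — they are excluded by the |log₂FC| ≤ 5 display mask rather
  than patched with pseudocounts.
- Cohorts are never pooled: each cohort is analyzed as its own two-group
  comparison.

Validation measures type-I calibration (null 6 vs 6, fraction of p < 0.05
within three binomial SDs of 0.05; KS uniformity) and recovery of a planted
log₂FC grid {−2, −1, 0, +1, +2}. Grid effects are planted in symmetric ±
pairs covering 20% of genes: a one-sided bulk shift is absorbed into any
median-based normalization by construction, so a recovery experiment must
keep the normalization reference null-dominated — this is a property of
median-of-ratios normalization, not of this implementation.

## Small-RNA quantification

Reads are filtered so every base is ≥ Q30 (inclusive; fraction
configurable), the 3′ adapter is located by the leftmost exact match of the
first 8 nt of its invariant portion, everything from the adapter on is
removed, and the four randomized ligation nucleotides on each side of the
insert are stripped; inserts shorter than 16 nt (pre-strip: 24 nt including
flanks) are dropped and tallied. The first k nt of each insert (k = 19 or
18 by library convention, one parameter) are matched exactly against the
dictionary. Dictionary load normalizes U→T, strips chemistry annotations
(leading `App`, trailing `ddC`), and refuses k-prefix collisions between
distinct sequences; identical full sequences (paralog duplicates) are
collapsed into one multi-id entry only behind an explicit flag — silent
double counting is worse than a loud failure. Spike-ins and size standards
are counted but removed from biological totals. Read accounting
(filtered + dropped + matched + removed + unmatched = input) is asserted at
run time. CPM divides each normalized count by the sample's normalized
total and multiplies by 10⁶ — the only reading of "per million" that makes
columns sum to 10⁶.

## Intervals and counting

GTF exon features (1-based inclusive) are converted to 0-based half-open at
the I/O boundary; all internal coordinates are 0-based half-open. The exon
union is the interval union over all transcripts; the gene span is min exon
start to max exon end; the intron union is span minus exon union (empty for
single-exon genes). The counter is union-mode, single-end: a read counts to
a gene if any aligned block overlaps the gene's interval set and the strand
rule passes (0 ignore, 1 same, 2 opposite); reads hitting ≥ 2 genes are
discarded as ambiguous. This standardizes on one ambiguity rule where
published pipelines have mixed two tools' semantics; it is validated
exactly against an exhaustive per-base oracle.

## Concordance and downstream statistics

- Exon/intron concordance: Pearson R² of paired log₂ fold changes, sign
  quadrant counts, and Fisher tests of up/down DE-call overlap with the
  intersection universe (genes testable on both axes) as background.
- Regulatory-mode classifier (`classify_regulation`): a gene is
  *transcriptional* when its intron axis is called (unadjusted p < α) in
  the exon direction, else *post-transcriptional* when its exon axis is
  called, else *unchanged*. Unadjusted p-values are used because the
  classifier describes individual genes of interest rather than controlling
  a genome-wide error rate; with the default generator (dispersion
  asymptote 0.02, 8 replicates/group, intron counts at 20% of exon
  baseline) the planted modes are separated with ≥ 95% accuracy, and the
  pre-chosen acceptance bar is 90%.
- Gene-set shift: Welch (unequal-variance) unpaired t-test on two disjoint
  sets' fold changes — Welch because equal variances cannot be assumed
  between, e.g., epithelial and mesenchymal signature sets; a
  pooled-variance variant would be a one-line change.
- Cross-genotype regression: OLS of one comparison's log₂ fold changes on
  another's over genes with ≥ 50 mean raw counts on both axes; t-based 95%
  CI. OLS (not orthogonal) regression is used; since x is itself an
  estimate, the slope attenuates by σ²ₛᵢ𝗀ₙₐₗ/(σ²ₛᵢ𝗀ₙₐₗ+σ²ₙₒᵢₛₑ). The
  validation configuration therefore plants a wide effect spread
  (signal variance ≈ 1) at 8 replicates/group (per-gene noise
  variance ≈ 0.01), making the attenuation ≲ 0.02 — well inside the ±0.03
  recovery tolerance. On real data with slope near 1 the OLS/orthogonal
  distinction is similarly minor.
- Variable-gene PCA: per-sample scaling to 10⁴ total, log1p, gene ranking
  by variance of the log-normalized values, z-scaling of the top 2000 with
  |z| clipped at 10, PCA with (samples − 1) components. This is a compact
  re-expression of the common single-cell-workflow defaults; validation
  uses group-separation properties, never absolute score values.

## The synthetic-data generator

The generator emulates the input landscape of a two-genotype (plus control)
pituitary study: exon and intron count matrices sharing genes and library
factors, a small-RNA library, a UTR-length table, a prediction table, and a
miRNA dictionary with spike-ins. Defaults are study-scale choices fixed
once:

| parameter | default | why |
|---|---|---|
| genes | 2000 | desk-scale while keeping binomial/KS tests well-powered |
| replicates/group | 4 | the 3–4 biological replicates typical of such studies |
| dispersion trend (a₀, a₁) | (0.02, 1.5) | isogenic-mouse bulk tissue replicates; α(μ)=a₀+a₁/μ |
| baseline expression | log-normal, median ≈ 256 counts | spans the filter boundary realistically |
| library sizes | uniform 0.8–1.3 M | ±20% depth variation, fixed per sample across exon/intron matrices (same library) |
| intron baseline | 20% of exon | intronic reads are sparse; a free parameter, not calibrated to any particular library |
| tf_log2fc | −1.0 | strong transcriptional repression of TF-target genes (applied to exons *and* introns) |
| mir_log2fc | log₂(1.25) | the modest derepression scale of losing one miRNA family (exons only) |
| utr_length_bias | 0.5 | targets ~1.5× longer UTRs — the confound that motivates matching |
| miR-200-like families | 5×/10× abundance drop (het/hom) | mirrors the measured family collapse |
| read structure | 4 random nt + mature + 4 random nt + 3′ adapter, Q37 with a 5% one-low-base fraction | exercises flank stripping and the Q30 filter |
| spike-ins | 1% each, synthetic sequences | accounting controls; sequences are invented, labelled synthetic |

Randomness flows through named streams (`structure`, `library`, `exon`,
`intron`, `reads`, `utr`, `predictions`) derived from the master seed, so
adding one output never perturbs another and everything is byte-reproducible
from (config, seed). UTR lengths are assigned at gene-structure time and
stored in the planted truth (so planted fold changes may depend on them);
`simulate_utr_table` exports them in the two-column input format.
`utr_lfc_per_log2` plants a target-independent, length-proportional exon
fold change used only by the confound experiment. `group_effect_scale`
scales all planted effects per group (e.g. hom = 1.1 × het for the
regression experiment).

**What the generator does not emulate** — and hence what passing tests do
not certify about real data: fragment-level biases (GC, positional),
multimapping and alignment artifacts, isomiRs and mismatch-tolerant
matching, batch structure beyond a single cohort label, dispersion outliers
beyond the fitted trend, and correlation between targeting strength and
expression level. Prediction scores are independent of planted effects by
default; the score-ordered monotonicity property is exercised with
score-coupled effects constructed in the tests.

## Numerical and procedural choices

- All count I/O is TSV; FASTQ is Phred+33; coordinates in interval outputs
  are 0-based half-open.
- Quantile-bin ties, top-set ties and sorting are all broken by stable gene
  id, making every result permutation-invariant and deterministic.
- BH adjustment is *not* idempotent on its own output (re-adjusting
  inflates values again); the implementation makes no such claim and the
  tests assert the true properties: domination of the input, monotonicity
  in sorted order, cap at 1, NA propagation.
- Validation problem sizes (50 pipeline repetitions for calibration and
  recovery, 20 for the confound and regression experiments, 10⁵ reads,
  10⁴ reads against the per-base oracle) were chosen once to leave ≥3-SD
  margins on every stochastic bound.

## Known limitations

- The NB engine intentionally omits empirical-Bayes dispersion moderation,
  outlier replacement and independent filtering; its p-values are slightly
  noisier than the reference tools' at very small replicate counts.
- The counter takes single-end records only; paired-end handling is out of
  scope.
- Target prediction itself (site finding, context++ scoring, conservation
  calls) is out of scope; prediction tables are inputs.
- The Mann–Whitney exact path requires a tie-free pooled sample; fold
  changes from continuous estimates make ties measure-zero in practice, but
  heavily rounded inputs will silently use the corrected normal
  approximation.
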