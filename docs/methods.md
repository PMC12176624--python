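# Methods

## Model and rationale

`escapeatlas` quantifies escape from X chromosome inactivation (XCI) in an
F1 hybrid mouse design with fully skewed XCI: the maternal (BL6) X carries
an *Xist* deletion and is therefore always active, the paternal (CAST) X
is always inactive. Every SNP-overlapping read is assignable to a parental
allele, and the allelic ratio of a gene,

    AR = maternal reads / (maternal + paternal reads),

directly measures the fraction of its expression originating from the
active X. AR = 1 means complete silencing of the inactive X (Xi); a gene
with AR ≤ 0.9 expresses at least 10% of its transcripts from the Xi and is
called an escapee. The Xi-expressed fraction is `1 − AR`.

The pipeline moves from per-SNP allele counts to five analysis layers:

1. **Gene-level allelic ratios** (`allelic`). SNP counts are filtered by a
   per-SNP read floor (`minread`, default 1), summed over the gene body
   ([start, end), 0-based half-open), and a replicate is *informative*
   when its total reaches the per-gene read cutoff (default 20 for bulk
   organs, 10 for sorted cell types, 20 for pseudobulk). The per-condition
   AR is the median over informative replicates; at least
   `min_informative_samples` (default 2 of 3) replicates are required.
2. **Escape calling** (`calling`). Inclusive comparison `median AR ≤ 0.9`
   in females. Genes biallelic in male single-X samples are excluded as
   probable mapping artifacts, as are pseudoautosomal genes and a small
   configured false-positive list (defaults: Mid1, G530011O06Rik, Gm39551,
   Gm14719, Armcx4, Sms, Llph-ps2). Percent escape uses genes with a
   defined call (escape or no-escape) as the denominator.
3. **Dynamics** (`dynamics`). Timepoints are categorical (embryonic,
   young, adult, aged). *Age-specific* escape means: escape in aged,
   silenced at every informative earlier timepoint, with at least one
   informative earlier timepoint — a gene non-informative at all earlier
   stages is *other*, because absence of evidence should not generate an
   age-specific claim. *Constitutive* means escape at every informative
   timepoint (≥ 2 informative). The *gradual biallelic trend*
   (ΔAR = AR_adult − AR_aged ≥ 0.1, informative at young, adult and aged)
   is an orthogonal flag: constitutive escapees can also drift.
   ΔAR endpoints are adult minus aged throughout the package.
4. **Positional statistics** (`windows`). Gene position is the annotation
   start everywhere, so clusters, windows and distances share one point
   per gene. Escape clusters are single-linkage chains with a 2.5-Mb gap.
   Aged-escapee enrichment is computed in 20-Mb windows sliding by 10 Mb
   (half-window overlap; the step is a package choice, with a disjoint
   mode available by setting step = window) and tested with an exact
   two-sided binomial against the chromosome-wide aged fraction. The
   distal test asks whether positions concentrate in the first 20 Mb plus
   the last 40 Mb of chrX (null probability = 60 Mb / 171,031,299).
5. **Allelic ATAC and single cells** (`atac`, `singlecell`). Peak identity
   comes from union-merging called peaks across samples (≥ 1 bp overlap);
   window assignment uses the peak midpoint so each peak counts once.
   Aged-peak enrichment per 10-Mb window is aged/(aged+adult) median peak
   counts with a one-sided exact binomial against p = 0.5 (equal peak
   numbers under the null). High-confidence Xi-opening peaks must be
   called in every aged replicate and shift by ΔAR ≥ 0.1 on median ARs.
   Cells are assigned an active X from the chromosome-wide AR over
   X-linked SNP reads (Xist-locus SNPs excludable): AR ≤ 0.2 → CAST Xa,
   AR ≥ 0.8 → BL6 Xa, in between biallelic, fewer than 10 X reads →
   unassigned. Pseudobulk pools allele counts over same-active-X cells per
   cluster, analyzed only when the cluster exceeds 50 such cells at every
   timepoint.

## Statistical conventions

- Two-sided exact binomial p-values use the minimum-likelihood convention
  (sum of all outcome probabilities not exceeding the observed one), the
  convention of `scipy.stats.binomtest` and R's `binom.test`, stated
  explicitly because implementations differ. One-sided tests are
  P(X ≥ observed).
- Fisher's exact test reports the cross-product odds ratio a·d/(b·c) with
  a Woolf logit 95% CI, and co-reports the conditional-MLE estimator,
  because published tools disagree on which estimator they print.
- Group comparisons default to nonparametric tests (two-sided
  Mann–Whitney U; Kruskal–Wallis with Dunn/BH post hoc co-reported next
  to ANOVA/Tukey) rather than switching on a normality pre-test — the
  deterministic choice is preferred over data-dependent test selection.
- Window p-values are reported per window (uncorrected), with BH q-values
  co-emitted.
- ATAC window medians over an even replicate count can be half-integer;
  they are rounded half-up before the binomial test, which needs integer
  counts.
- Undefined quantities (AR of a zero-count gene, fold change with a zero
  male median, odds ratio with an empty margin) are NaN sentinels, never
  silently 0.
- Boundary ties are resolved deterministically: AR exactly at the escape
  cutoff is escape (inclusive ≤); per-cell AR exactly 0.2 or 0.8 is the
  monoallelic call.

## Synthetic data generator

The generator (`simulate`) produces the three study designs with planted
ground truth, so every stage is testable without sequencing data.

**Noise model.** Per-gene read totals are gamma-Poisson (negative
binomial, shape 5) around `depth_mean` (default 200 reads/gene) and split
across the gene's SNPs (1 + Poisson, mean 5 SNPs/gene). Paternal (Xi)
reads are beta-binomial: one Beta draw per gene × sample with mean equal
to the true Xi fraction and intra-class correlation `overdispersion_rho`
(default 0.02), shared across the gene's SNPs so the gene-level counts
are exactly beta-binomial. Silenced genes leak `leak_epsilon` = 0.005 of
their expression from the Xi; escapees draw their Xi fraction uniformly
from [0.10, 0.50]. Male samples carry one maternal X and emit no paternal
reads (optional planted mapping-bias genes exercise the male exclusion
filter).

**Escape truth.** A two-level model: each gene is globally escape-prone
(probability 0.035/0.64), aging-susceptible (0.031/0.372), or silenced;
a prone gene expresses escape in each organ with penetrance 0.64
(constitutive) or 0.372 (aged-only gains). The two penetrances are
derived from the emulated regime so that both the per-organ escape rates
(≈ 3.5% adult, ≈ 6.6% aged) and the cross-organ union sizes (≈ 21
constitutive escapees, ≈ 31 age-specific) come out right at once — a
model where organs gain escape independently cannot match both.
Aging-susceptible genes are placed in the distal head/tail regions with
probability `distal_bias_w` = 0.8.

**Design sizes.** Seven organs × {young, adult, aged} × both sexes × 3
replicates, plus female-only embryonic samples for five organs — the bulk
design. Single cells: 2,000 adult + 1,500 aged cells over seven cardiac
clusters whose composition shifts with age (cardiomyocytes 30.4% → 25.0%,
fibroblasts 22.0% → 32.3%), strain-skewed random XCI (60% CAST-active),
mean 50 X-linked reads per cell. ATAC: 300 background peaks plus 30
planted Xi-opening peaks (half de novo, half switching from Xa-specific),
2 replicates per timepoint, depth 100. These sizes are the package's
default working scale; they are deliberately smaller than a full
sequencing study while preserving each design's structure.

**What the generator does not emulate.** Genes occupy disjoint genomic
slots — real annotations contain overlapping genes whose shared SNPs
would blur per-gene truth; this choice makes planted truth identifiable
but means the pipeline's behavior on overlapping loci (e.g. nested or
antisense genes) is untested here. There is no read-level error, mapping
bias (beyond the optional planted male-bias genes), expression-level
variation between organs, or cell-type-specific expression of individual
genes. Passing recovery tests therefore demonstrates the correctness of
the statistical machinery under the declared noise model, not robustness
to alignment artifacts.

**Determinism.** All randomness flows from one
`numpy.random.Generator(seed)`; identical configurations produce
byte-identical outputs. The single-cell and ATAC generators offset the
seed by fixed constants so the three designs are independent but jointly
reproducible.

## Numerical and degenerate-input choices

- Windows at the chromosome end are truncated at `chrom_length`; an empty
  window reports NaN enrichment and p = 1.
- If every escapee (or none) is aged-identified, the sliding-window
  contrast is degenerate and all windows report p = 1 rather than erroring.
- `aggregate_gene_counts` reports (0, 0) for genes with no retained SNP,
  and is additive over any partition of the SNP table.
- Config round-trips exactly through YAML/JSON; unknown keys are rejected
  so typos cannot silently revert a threshold to its default.

## Known limitations

- Escape recall on planted data is ≈ 0.95–0.96, limited by planted Xi
  fractions just above 0.10 whose true median AR sits at the inclusive
  cutoff; these genes are missed half the time by symmetric noise. This
  is a property of the cutoff design, not of the implementation.
- The male-biallelic exclusion uses the same-timepoint male median when
  informative and otherwise the minimum across timepoints of the group —
  a global exclusion in spirit; per-timepoint-only exclusion is not
  offered.
- Pseudobulk escape calls have a single pooled observation per cluster ×
  timepoint, so their "informativeness" is a read-depth statement only;
  no male counterpart exists and the bulk-derived exclusion list is
  applied instead.
- Timepoints are categorical; no longitudinal or survival modeling.
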