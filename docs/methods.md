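# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Design and notation

Samples carry one of four genotype labels: `Z+` (treatment transgene, the
group whose specific dysregulation is sought), `A+` (control transgene),
and the non-transgenic backgrounds `Z-` and `A-`; the reference design is
six biological replicates per group. Transcripts are quantified as raw
counts, proteins as non-negative intensities, both features × samples.

## Matrix preparation

- **Consolidation.** Transcript-level counts are summed into genes through
  a feature→gene map; unmapped features are an error (silently dropping
  counts would bias library sizes). Column totals are conserved exactly.
- **Low-expression filter.** A gene is kept when its raw count exceeds 100
  in at least 3 non-outlier samples. The comparison is strict (`> 100`);
  the boundary is configurable. The same rule screens protein intensities.
- **RPKM.** `count / (length/10³) / (library/10⁶)`. Library size is the
  column sum of the *pre-filter* consolidated matrix, so normalisation does
  not depend on the filter, and counts library-assigned (feature-assigned)
  reads, the only total recoverable from a count matrix.
- **log2 transform.** `log2(RPKM + 1)`. The pseudocount of 1 handles zeros
  while leaving RPKM = 1 at log 1; it is configurable. A unit tag on the
  matrix prevents double transformation.
- **Outlier screen.** Default rule: flag a sample whose log10 library size
  deviates from its genotype median by more than k = 3 median absolute
  deviations *and* by more than 0.1 log10 units (~26 %). The absolute floor
  exists because in tight groups the MAD can be minuscule and k·MAD alone
  would flag ordinary sampling noise. A median-Spearman-correlation screen
  is available as an alternative. Flagging may not reduce any genotype
  below two samples. Flagged samples stay in the matrices but are excluded
  from every downstream statistic.

## Differential calling

Equal-variance two-sided Student's *t* per feature for the four contrasts
(contrast 2 pools the twelve `Z-`/`A-` samples). Degenerate features with
zero pooled variance get (t = 0, p = 1) when means agree and (t = ±∞,
p = 0) otherwise. Welch's test is available behind a flag for sensitivity
analyses. p-values are adjusted per contrast across all features with
Benjamini–Hochberg (delegated to statsmodels; an independent step-up oracle
guards it in the tests).

The decision rule combines the contrasts into one call:

    is_deg ⇔ q₁ + q₂ + q₃ ≤ τ  ∧  q₄ > α  ∧  sign(LFC₁) = sign(LFC₂) = sign(LFC₃) ≠ 0

The summed-q statistic is the simplest scalar reading of "jointly small
FDR across the treatment contrasts"; the q₄ veto removes features that
also differ between the two non-treatment genotypes (a background rather
than treatment effect); the sign-consistency requirement makes the reported
direction well defined. Defaults: τ = 0.15 and α = 0.05 for transcripts;
τ = 0.3 for proteins, where smaller effective sample sizes warrant lower
stringency. These defaults are this package's explicit choices: the rule's
exact historical parameterisation is not standardised, so both thresholds
are first-class config keys, and the monotonicity of the rule (lowering any
qᵢ, i ≤ 3, or raising q₄ can only add calls) is property-tested.

Calibration under the null and power at the design point are not assumed
but measured: with nothing planted (10,000 genes, n = 6, 20 seeds) the
false-positive fraction is ~0 (≤ 1 % required); with 2–7-fold `Z+`-only
effects planted on well-expressed genes, aggregate sensitivity is ≈ 99 %
with empirical FDR ≈ 2 % (≥ 80 % / ≤ 10 % required).

## Cross-omics

Proteins are matched to transcripts through a protein→gene map; the overlap
fraction is matched/total proteins. The correlation is a single Pearson r
pooled over all (gene, sample) points — transcript axis log2(RPKM + 1),
protein axis log2(intensity + 1) — matching how such scatterplots are
drawn; a per-gene-then-average mode exists behind a flag because the pooled
estimate is dominated by between-gene spread. DEG/DEP intersection maps
proteins into gene space first; with many-to-one paralog maps a protein
matches if *any* source gene is a DEG.

## Enrichment

Differential ids are mapped to the annotation id space through the ortholog
map before lookup; paralogs collapsing onto one target gene are
de-duplicated before computing k (differential genes in the term) and n
(mapped differential genes). If merged paralogs disagree in direction the
target gene is direction-conflicting and renders its terms `mixed`. The
score is the frequency ratio (k/n)/(K/N) with background N = all genes
annotated in the category's database (the most conservative self-contained
universe; "all expressed genes" can be passed instead). Over-representation
is score > 1 — a ratio, not a test; the hypergeometric upper-tail p is
emitted as an optional column and never used as a filter. Mapping rates are
percentages rounded half-up to one decimal, computed with exact rational
arithmetic so formatting is reproducible.

## Term networks

Nodes are enriched terms (score and direction as attributes — the usual
size/colour encodings); an edge joins any two terms sharing ≥ 1
differential gene, weighted by the count shared. The transcript-level map
filters on score strictly > 4 with uniformly directed members; the
protein-level variant only requires uniform direction. Terms sharing
nothing remain as isolated nodes. Construction is order-invariant and is
tested against an O(T²) pairwise-intersection oracle. GraphML export
round-trips through the bundled reader.

## qPCR

ΔCt = mean Ct(target) − geometric mean of the per-housekeeping-gene mean
Cts (arithmetic mean behind a flag); relative expression = 2^−ΔCt × 10,000.
Fold changes compare genotype means of relative expression. Validation
against RNA-seq fold changes uses Spearman's ρ with average ranks for ties;
the p-value is an exact two-sided permutation enumeration for n ≤ 8 genes
(≤ 40,320 permutations) and the t approximation above that.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions the pipeline assumes.

- **Counts.** Negative binomial with variance m + φm² (φ = 0.05, a typical
  bulk RNA-seq overdispersion for biological replicates), gene-wise
  baseline means log-normal (ln-mean 5.5, ln-sd 1.5: median ≈ 250 counts,
  a realistic bulk dynamic range). Planted fold changes divide (down) or
  multiply (up) the NB mean in `Z+` columns only — 100 suppressed and 100
  induced genes by default, folds uniform on [2, 7]. Planted genes are
  drawn among genes whose baseline clears 200 counts: an effect planted
  below the detection filter is unrecoverable by design, and the pathway
  genes such studies validate are well expressed. Baseline means come from
  a named child RNG of the master seed so `default_config` and
  `generate_counts` see identical values.
- **Proteome.** For ~4000 genes drawn from those passing the detection
  filter, log2 intensity = a·x + b_g + ε + offset, where x is the gene's
  log2(RPKM + 1) signal, b_g a gene-level decoupling offset and ε
  per-sample noise (sd 0.3). The variance of b_g is solved so the pooled
  (gene, sample) Pearson correlation equals the target (0.22 by default);
  the drawn offsets are then orthogonalised against the gene means and
  rescaled to the solved variance, so the target is realised in-sample
  rather than only in expectation (realized |r − 0.22| < 0.001 at 4000
  pairs). Placing the decoupling *between* genes reflects how translation
  efficiency and turnover act, and leaves within-gene dynamics coupled, so
  planted protein-specific effects (40 down + 40 up by default, applied
  multiplicatively in `Z+` only, on genes disjoint from the
  transcript-planted sets) remain detectable. The disjointness emulates
  post-transcriptionally regulated proteins: DEG and DEP lists do not
  overlap. The additive offset (40 log2 units) keeps all intensities far
  above the +1 pseudocount so the measurement axis is faithful to the
  model; intensities are synthetic and unitless.
- **Annotations and orthologs.** The ortholog map sends model-organism
  genes to human ids with ~10 % consecutive-pair paralogs (many-to-one).
  Term databases (250 GO-BP-like, 120 KEGG-like terms of 5–50 genes) are
  uniform draws from the mapped universe, plus one planted term per
  direction per category composed 80 % of planted-gene images.
- **qPCR.** Target genes get a baseline Ct (24–28 cycles), shifted by
  −LFC in `Z+` samples (one cycle per doubling); two housekeeping genes sit
  at fixed Cts; N(0, noise_sd) is added to every measurement (default
  0.2 cycles, a typical technical replicate sd), two technical replicates
  per (gene, sample).
- **Outlier emulation.** An optional count of samples is binomially thinned
  to 10 % depth to exercise the screen.

Everything derives from one integer seed through named `SeedSequence`
children, so outputs are bit-identical across runs.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: GC/length biases and mappability, batch and
lane effects, correlated gene modules (genes are independent given their
means), compositional effects of extreme regulation on library size,
protein-inference ambiguity and missingness-not-at-random in proteomics,
and primer-efficiency deviations in qPCR.

## Problem sizes and runtime

Default synthetic studies use 6,000 genes × 24 samples and 4,000 proteins —
large enough for stable BH behaviour and ≥ 4,000 matched cross-omics pairs,
small enough that the full test suite runs in ~20 s and the acceptance
script in ~10 s. Null calibration uses 10,000 genes × 20 seeds. Scaling to
the full ~28k-gene design is a config change (`n_genes`), not a code
change; all operations are vectorised across features.

## Known limitations

- Equal-variance Student's t with per-gene variance only; no moderated
  (shrunken) variance, so power at very small n is below limma-style
  callers.
- The summed-FDR rule is a heuristic combination; its thresholds are
  calibrated empirically on the synthetic design, not derived from a
  formal FDR guarantee on the sum.
- RPKM is the only normalisation (no TMM/median-of-ratios size factors);
  strongly asymmetric regulation would bias it.
- The enrichment background defaults to the annotated universe, which can
  overstate scores when annotation coverage is much smaller than the
  expressed genome; pass an expressed-gene background where that matters.
- GO graph structure is ignored: terms are independent gene sets, with no
  ancestor propagation.
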