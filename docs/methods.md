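# Methods

This note documents the models and procedures implemented in `epimark`, the
choices made where the design was genuinely open, and what the synthetic-data
tests do and do not demonstrate about real data.

## Problem setting

Regulatory annotation (histone-mark ChIP-seq peaks) is abundant for human but
sparse for most other mammals. The workflow implemented here borrows human
annotation for a target genome (the motivating case is cattle) in four steps:

1. **Liftover** — peak intervals are projected through pairwise alignment
   chains onto the target genome, and the per-mark *transfer efficiency*
   (fraction of peaks successfully mapped) is reported.
2. **Aggregation** — per-sample peaks become a features × samples signal
   matrix over gene-anchored windows: promoter windows for promoter marks
   (H3K4me3, H3K27ac), length-normalised gene bodies for H3K36me3.
3. **Tissue specificity** — each feature × tissue combination is scored with
   the t-statistic of a ±1-coded OLS fit, with biologically related tissues
   excluded from the comparison group; the top k% of features per tissue form
   its tissue-specific set.
4. **Enrichment and concordance** — GWAS or selection-scan statistics are
   tested for concentration in those sets with a sum-based marker-set
   statistic under a circular permutation null; the resulting trait × tissue
   enrichment profiles are correlated across traits, and specificity
   t-vectors are correlated across modalities (histone vs expression vs
   promoter methylation).

## Coordinate conventions

All internal intervals are 0-based half-open (BED). GTF input is converted on
read. GWAS marker positions stay 1-based in their `pos` column; membership in
an interval uses `pos − 1 ∈ [start, end)`. Chromosome order for the circular
marker index is explicit configuration, never inferred, so the permutation
null is reproducible.

## Liftover

Chain files are expanded to explicit ungapped blocks; negative-strand target
chains are converted to forward-strand coordinates with the strand recorded.
An interval maps when one dominant chain covers ≥ `min_map_ratio` (default
0.5) of its bases with a single target chromosome and strand. The target is
the minimal interval spanning the mapped pieces, rejected (`split_rejected`)
if it exceeds twice the source length — this caps expansion across long
target-side gaps. Pieces scattered over several chains with no dominant one
are likewise `split_rejected`; anything under the coverage threshold is
`unmapped`. Transfer efficiency is a peak-count fraction by default; a
base-pair-weighted variant is available (`weight="bp"`) since either reading
of "fraction transferred" is defensible.

## Signal aggregation

Promoter windows are −1000/+500 bp around the TSS (annotation start on +,
annotation end on −), clipped at chromosome edges. Gene bodies shorter than
750 bp are excluded. The default promoter weighting credits a peak with
`signal × overlap/peak_length` — the fraction of the peak's signal mass
falling in the window. Because narrowPeak `signalValue` is a per-base
density, the quantity that is additive under splitting a peak into abutting
pieces is `signal × overlap_bp` (mode `"bp"`); binary occupancy is also
available. The default follows the mass-fraction reading; the mode is a
parameter because no operational definition of "signal intensity in the
promoter" is canonical. Gene-body aggregation is `Σ signal × overlap_bp`
per kb of gene length.

## Tissue-specificity model

For feature signal y over samples, tissue effect b is estimated by OLS on

    y = μ + X b (+ Z c) + e

where X codes tested-tissue samples +1 and the rest −1, and Z holds optional
categorical covariates (age, sex, study) as reference-level dummies. The
specificity score is t = b/se(b); with no covariates this is algebraically
the pooled two-sample t-test (verified to 1e-10 against an independent
implementation). Before fitting, all samples whose *exclusion class* matches
the tested tissue's class are removed from the comparison group — testing B
cells excludes T cells and thymus when all three share an immune-blood class
— so related tissues cannot mask each other's specificity. The 33→23-style
tissue-class collapse is user data (a two-column mapping), not code.

Numerical choices: features whose residual variance is numerically zero
(relative tolerance 1e-12 against the feature's own mean square) get t = 0
rather than NaN, keeping matrices dense and ranking such features last.
Fits are vectorised across features per tissue (one shared design matrix,
one solve); rank-deficient designs are rejected naming the collinear factors.

Expression input (log2FPKM) is standardised per sample (mean 0, sd 1 across
genes) by default; a per-tissue pooled variant exists because the appropriate
scaling scope is ambiguous with few samples per tissue. Promoter methylation
uses the coverage-weighted level Σ meth / Σ total over the window's CpGs
(so (1/1) + (0/9) → 0.1, not the naive CpG mean 0.5); windows with no
covered CpG are missing, not zero — zero would assert full unmethylation.
Methylation specificity inverts the coding (−1 tested / +1 rest) so
tissue-specific *hypo*methylation scores positive, mirroring its negative
association with expression.

Top-k% sets take the ceil(k·n) features with largest t, ties broken by
feature id for determinism; k defaults to 0.05 with 0.03 and 0.10 as the
conventional alternatives.

## Enrichment test

For a marker set S (markers inside a tissue's top regions) the statistic is
T = Σ_{i∈S} stat_i² (squared statistics are the default; |t| and −log10 p are
modes, since "sum-based" admits several conventions). The null rotates the
whole genome-ordered statistic vector by one global offset k ∈ {1,…,m−1} per
permutation — a rigid rotation preserves the local correlation structure of
the statistics, which is precisely what this null must respect; independent
per-chromosome rotation is available behind the same interface by testing
chromosomes separately. Empirical p uses the add-one formula
(#{null ≥ T} + 1)/(n_perm + 1), guaranteeing validity; exhaustive enumeration
of all m−1 offsets is used when affordable. A set covering all markers is
rotation-invariant and reported p = 1 with a warning; an empty set is a
missing profile cell, never p = 1.

Profiles collect −log10 p over traits × tissues; Benjamini–Hochberg q-values
are computed matrix-wide per mark/cutoff (matching a one-heatmap-one-FDR
presentation; per-trait correction is a flag). Selection-scan statistics are
ingested as a GWAS table whose `stat` column is the scan statistic — the
machinery is identical.

## Concordance

Cross-modality comparison correlates tissue-specificity t-vectors over shared
features (Pearson, p from the t-transform with df = n−2, BH over all cells;
the star threshold defaults to q < 0.001 for modality validation and 0.05
for trait–trait profiles). Trait–trait comparison correlates −log10 p
enrichment profiles over an explicit pairing of comparable tissue labels;
missing cells drop pairwise with n recorded. The interval-overlap test
places each query segment uniformly at random inside a workspace (lengths
preserved, placements independent, the simplest uniform sampler) and compares
observed annotation overlap against the permuted distribution; single-segment
queries support exact enumeration of all placements.

## Synthetic data: what it emulates

`SimulationSpec` holds every constant; generators are pure functions of
(spec, seed) with per-stage independent streams (fixed stage keys spawn the
generator, so adding a stage never shifts another's draws).

Reference conditions (the defaults): 2 chromosomes × 10 Mb; 2000
non-overlapping protein-coding genes of 1–5 kb; 10 tissues × 5 samples;
130 planted tissue-specific genes per tissue, disjoint across tissues; peak
signal Lognormal(0, 0.5) with planted signals multiplied so the expected
tested-vs-rest difference is 3 within-group sd; peak boundaries jittered
±200 bp; 2000 evenly spaced markers with N(0,1) statistics shifted by 2 in
planted regions; chain coverage 0.8 in 10-kb periods (nested across
coverages, so efficiency is deterministically monotone); methylation
Beta(2,8) (planted, own tissue) vs Beta(8,2), 10 CpGs per promoter at
Poisson(10) depth; expression baselines N(5,2) with unit noise. These sizes
were chosen as the smallest at which the statistical properties under test
(calibration bands, recovery rates, correlation targets) have comfortable
sampling margins.

The cross-modality correlation target `rho_modality` is hit by co-planting:
each tissue's expression-planted set reuses the histone-planted gene with a
probability f derived in closed form from the three-class mixture of
per-gene t moments (planted; planted in another tissue, whose elevated
samples contaminate the comparison group with a negative mean shift and
damped variance; unplanted). The derivation lives in
`epimark.synthetic.coplant_fraction`; realized matched-tissue correlations
at the default geometry fall within a few hundredths of the target.

What passing these tests does *not* show about real data: synthetic peaks
have no width/shape structure beyond jitter, no correlated replicate noise,
no LD beyond an optional AR(1) stress mode, uniform marker density, and no
batch effects except the covariates the expression model injects. The suite
demonstrates correctness and calibration of the machinery, not biological
sensitivity at genome scale; the printed efficiencies and correlations of
any real study depend on genome-scale inputs the desk-scale demo does not
model.

## Pipeline and reproducibility

Stages exchange only on-disk artifacts in the documented formats. The demo
configuration (2 × 2 Mb, 240 genes, 5 tissues × 3 samples, 6 traits, 500
permutations) runs in seconds and exercises every stage; `manifest.json`
records the config snapshot, seeds and sha256 digests of all inputs and
outputs with relative paths and no timestamps, so identical configurations
reproduce byte-identical manifests. `scripts/acceptance.py` regenerates all
headline quantities from scratch at a caller-supplied seed; its problem
sizes (1000 OLS partitions; 200 permutation configs at m ≤ 500; 1000 null
and 200 alternative enrichment replicates; 1000-gene recovery; 2000-gene
modality recovery with 20 null seeds) are the same conditions the acceptance
tests assert against.

## Known limitations

- The liftover acceptance rule is a documented surrogate for CrossMap's
  (dominant chain, ≥ 50% bases, single chromosome/strand, ≤ 2× span); real
  tools differ in edge cases such as split mappings.
- The specificity model assumes homoscedastic residuals across samples; no
  moderated/shrinkage variance estimator is provided.
- The overlap test's uniform sampler ignores composition (GC/isochore)
  matching.
- Methylation features uncovered in *any* sample are dropped whole-row
  before fitting rather than per-tissue.
- The enrichment statistic treats markers as exchangeable under rotation;
  systematic density gradients along the genome would violate that.
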