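# Methods

## Quantification model

Reads are aligned to hairpin precursor sequences upstream of this package;
only primary mapped alignments are consumed (a default-settings BWA run
reports one best hit per read). All in-memory coordinates are 0-based
half-open, converted once from SAM at the boundary.

**Adapter trimming.** A 3' adapter occurrence is searched by an exhaustive
cut-point scan: for every cut position the read suffix is aligned against
adapter prefixes with unit-cost mismatches, insertions and deletions, and a
candidate is acceptable when its edit distance is at most
`floor(max_error_rate × matched_adapter_length)` (default rate 0.15). Among
acceptable candidates the one explaining the most adapter bases net of
errors wins, ties broken by fewest errors, then leftmost cut — so a
full-length occurrence beats a spurious one-base suffix match, while genuine
partial occurrences at the read end are still trimmed. Inserts shorter than
14 nt are flagged discarded. The scan is O(read × adapter) per cut point;
fidelity was preferred over speed at desk scale.

**Arm assignment.** For precursors with annotated arms (knowledge-based
path) a read is assigned to the arm with the larger base-pair overlap; zero
overlap with both arms is `no_overlap`, equal positive overlap `ambiguous`.
For unannotated precursors (position-based path) the read midpoint strictly
below the precursor midpoint gives `-5p`, strictly above `-3p`, exactly
equal `ambiguous`. Ambiguous and non-overlapping reads are dropped, never
fractionally counted, so per-sample accounting is exact
(assigned + unassigned = input) and the drop rate is visible in the
assignment log. The arm-overlap rule and the midpoint split are design
choices where several readings were possible; maximal overlap and the
symmetric, parameter-free midpoint were chosen and are exercised by a
property test showing both paths agree whenever annotated arms exactly tile
the two hairpin halves.

Every precursor contributes both `-5p` and `-3p` rows to the matrix whether
or not reads support them, so the matrix has exactly 2 × n_precursors rows.

## Cohort categorization

Categorizers are total and idempotent. Points of note:

* BMI 30.0 is classified obese (inclusive boundary, matching WHO).
* Heavy smoking is ≥ 16 cigarettes/day (boundary inclusive).
* Alcohol: high intake strictly above 24 g/day (men) / 12 g/day (women);
  0 g/day is non-drinker.
* Coffee: the low/high cutoff is a parameter (default 8 g/day; 16 g/day is
  an equally defensible published convention and is supported via the same
  parameter).
* Age tertiles use empirical quantiles with linear interpolation; subjects
  exactly at a breakpoint fall in the lower class. The tie rule is explicit
  configuration because overlapping class labels make it ambiguous in
  published summaries.
* The physical activity index (PAI) sums recreational and household
  MET-hours/week (equal weight), quartiles the total within sex (linear
  interpolation, ties down), and cross-classifies quartile × occupational
  class through an editable table following the EPIC/Cambridge-index
  convention: heavier occupation shifts the category up and heavy manual
  work is "active" regardless of quartile. The exact published table is not
  available, so the shipped default was tuned once to reproduce realistic
  marginals (~27/34/32/6% inactive→active) and all PAI behaviour is
  conditional on that table.

## Normalization and variability

Size factors use the median-of-ratios estimator (geometric-mean reference
row over rows positive in all samples; a positive-subset fallback with a
warning handles sparse matrices), rescaled to geometric mean 1.
"Normalized reads" always means counts / s_j; the convention is adopted
pipeline-wide because the DE stage assumes it.

The robust CV is MAD/median of normalized expression, computed only where
the median is ≥ 1. The MAD is the raw median absolute deviation about the
median with **no** 1.4826 consistency constant — the statistic is defined
literally as the ratio. Because "MAD" is sometimes read as the *mean*
absolute deviation, a `mad_kind` switch provides that variant; the median
form is the default as it pairs naturally with the median denominator. Ties
in the CV ranking break by miRNA name for determinism.

Spearman correlations use average ranks; p-values come from the exact
permutation distribution for n ≤ 9 and the t approximation above. The
paired Wilcoxon test drops zero differences, uses tie-aware average ranks,
and computes the exact null distribution of the positive-rank sum (by
convolution, equivalent to enumerating all 2^n sign vectors) up to n = 25
informative pairs; above that a tie-corrected normal approximation with
continuity correction is used. The two branches agree to < 0.01 at the
boundary.

## Differential expression

Counts per miRNA follow NB(μ, α) with Var = μ + αμ², log link and offset
log s_j. The design is intercept + contrast indicator + adjustment
covariates (numeric covariates centered, categorical ones dummy-coded) +
library-pool dummies as fixed effects (pre-correction would be an
alternative; fixed effects keep the model explicit). Subjects outside the
two contrast levels or missing a required covariate are dropped from that
contrast only.

Dispersion α is estimated per miRNA by method of moments on normalized
counts within the categorical design cells (cells under 2 samples fall back
to a pooled estimate), floored at 1e-8 and capped at 10, then shrunk
halfway (in log space) toward a log-log mean–dispersion trend fitted across
miRNAs. This is a deliberately simplified stand-in for a full
empirical-Bayes dispersion pipeline — no outlier refitting, no independent
filtering — and agreement with reference DE tools is claimed only at the
level of operating characteristics. With 2,000 null NB features (α = 0.3)
and 100 subjects, the measured type-I error at nominal 0.05 is ~0.04–0.05,
and planted |log2FC| = 2 effects on expressed features at 100 subjects per
group are recovered with sensitivity ≥ 0.95 at FDR < 0.1 (recomputed by
`scripts/acceptance.py`).

The Wald p-value is the two-sided normal tail of W = log2FC/SE (matching
the Wald convention; no likelihood-ratio test). BH adjustment is applied
within each contrast, not pooled across variables, because DE lists are
reported per comparison. The DEmiRNA call is `q < 0.05` AND median
normalized reads ≥ 10 in at least one of the two groups in the active
contrast. Flags mark non-converged fits and separated contrasts (one group
all zero).

Continuous covariates (age, BMI) are analysed by Spearman correlation over
miRNAs with median normalized reads ≥ 10, BH-adjusted across miRNAs, and
banded at ±0.2 with strict inequalities. Band membership and significance
are independent axes: a miRNA can be significant yet "unaltered".

The heatmap transform z-scores log10(normalized + 1) per miRNA and
clusters rows and columns agglomeratively (Euclidean, complete linkage by
default); zero-variance rows become zero rows and are flagged.

## Enrichment

Gene scores sum, over contributing miRNAs targeting a gene,
−sign(log2FC)·(−log10 q), with q floored at 1e-300. The negation encodes
repression. By default only DE-called miRNAs contribute; an all-miRNA mode
and a raw-p switch exist for sensitivity analysis, since the published
aggregation this stage emulates is not fully specified. Each gene set is
tested by logistic regression of membership on standardized scores
(standardization makes slopes comparable across contrasts); the Wald p on
the slope is BH-adjusted within each library. Quasi-separated fits
(diverging slope or exploding SE) fall back to an L2-penalized IRLS
(λ = 1e-4, intercept unpenalized) and are flagged. Null calibration
(random membership) yields uniform p-values by KS test.

## Synthetic data: what it does and does not emulate

The generator reproduces the statistical structure the analysis assumes:
long-tailed log-normal baseline abundances (σ = 2.5, giving the wide
per-sample detection spread seen in stool profiles), log-normal library
depths around 10.3 M reads with 0.92% of reads assigned to miRNAs,
NB noise with shared dispersion α = 0.3 by default, questionnaire
marginals matching the 335-subject study population (63.6% female, age
truncated-normal 44.7 ± 14.7 on [18, 81], menopause derived from age > 50),
24-plex library pools as the batch variable, planted log2-fold-change
effects recorded in a truth ledger, and six repeat subjects with log-normal
latent drift. Per-count alignments are placed inside the corresponding arm
(or strictly inside the corresponding hairpin half), making quantification
an exact inverse — the module's core oracle.

It does **not** simulate read-level sequence errors, adapter contamination
beyond a fixed suffix, isomiR structure, correlated miRNA co-expression, or
microbiome background. Passing tests therefore demonstrate correctness of
the pipeline's logic and its statistical operating characteristics under
the assumed model, not robustness to artefacts of real sequencing data.
Per-miRNA abundance defaults are calibrated only to summary statistics
(hundreds of miRNAs detected per sample at demo depth) and are tunable, not
ground truth.

## Problem sizes

The demonstration pipeline uses 200 precursors (400 mature names), 60
subjects at ~10 k assigned reads/sample, and three planted contrasts on
well-populated strata; the DE operating-characteristic suites use 2,000
features with 100–200 subjects. These sizes were chosen so the whole test
suite and acceptance script each complete in about a minute on one CPU
while leaving the statistical conclusions stable across seeds.

## Known limitations

* The NB Wald stage is not numerically interchangeable with empirical-Bayes
  DE implementations (no dispersion moderation across conditions, no
  shrunken fold changes, no outlier handling).
* The PAI cross-classification table and the enrichment score aggregation
  are reconstructions of under-specified published conventions; both are
  isolated behind configuration so alternatives can be swapped in.
* Exact Spearman permutation p-values are limited to n ≤ 9 by factorial
  growth; the paired Wilcoxon exact branch covers n ≤ 25.
* Position-based assignment drops midpoint-straddling reads as ambiguous;
  on real data this loses a small, logged fraction of reads that other
  pipelines may count once or twice.
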