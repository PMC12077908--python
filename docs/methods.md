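# Methods

This note records the statistical model behind each pipeline stage, the
conventions adopted where several defensible choices existed, what the
synthetic-data generator does and does not emulate, and known limitations.

## CSF proteomic pyroptosis activation score

**HD scaling.** Aptamer panels report relative fluorescence units whose
scale differs per analyte, so each protein is standardized against the
healthy-donor distribution: `z = (x − mean_HD) / sd_HD` with the sample SD
(ddof = 1). At least two HD samples are required; proteins with zero HD
variance have no HD-referenced scale and are excluded with a warning rather
than silently set to zero. Scaling is idempotent and absorbs any positive
per-protein affine transform of the raw values, so the downstream score is
invariant to per-analyte gain and offset.

**Global severity.** The three per-patient severity outcomes — brain-damage
severity (age-residualized cognitive + MRI volumetric decline), CombiWISE
severity (continuous 0–100 disability scale) and MS-DSS — arrive on
unrelated scales. "Scaled" is implemented as a z-score across the analyzed
MS cohort (ddof = 1), summed; the composite therefore has mean 0 over the
cohort. The reference population is configurable (pass a pre-scaled table)
but defaults to the cohort itself. An outcome constant across the cohort
makes the scaling undefined and is an error, not a zero.

**Protein selection.** Spearman rank correlation of each pathway protein's
HD-scaled level with the composite severity over the MS samples, two-sided,
retaining proteins with p < α (default 0.05) and weighting by the
correlation coefficient. Spearman is used because the score's published
severity associations are rank correlations and because it is invariant to
the monotone (exponential) scale of abundance data; the selection is robust
to whether raw or log abundances are supplied. No multiple-testing
correction is applied inside selection by default (a Benjamini–Hochberg
option exists); the score is a fixed, frozen panel once selected, and a
weights JSON lets a published panel be applied verbatim without
re-selection. Ordering is deterministic (by protein identifier).

**Score.** `score = Σ z_i · r_i` over the selected proteins — linear in the
scaled levels, permutation-invariant, with per-protein contributions
returned for audit. A sample missing any score protein is an error; nothing
is imputed. Yearly score change between two dated samples divides by the
elapsed time using a 365.25-day year (the convention for every per-year
rate in the package).

**Change analysis.** For paired baseline/on-therapy samples (≥ 3 pairs),
the per-protein mean change is standardized against the distribution of
mean changes over *all* measured proteins; |z| > 2 (strict) flags the
~5% extreme tail, which is what gets exported for enrichment. Each protein
is also tested with a one-sample Wilcoxon signed-rank test of zero change.
The exact null distribution of W⁺ is built by the generating-function
recursion for n ≤ 25 pairs; zeros are dropped, and tied absolute changes
are handled exactly by enumerating sign flips over the observed average
ranks (the distribution conditions on the tie pattern). Larger n falls back
to the tie-corrected normal approximation. Two-sided p = 2·P(W⁺ ≤ min(w,
total − w)), capped at 1; a protein with identically zero change has an
undefined test and is reported with p = 1 and a flag. BH adjustment is
applied across the panel. With a handful of pairs and thousands of
proteins, the exact p floor (2/2⁹ ≈ 0.0039 for 9 pairs) means no protein
can pass an FDR threshold of 0.05 — the analysis is deliberately honest
about that, and the extreme-tail export is the usable output.

## Disability-progression safety monitoring

**Slopes.** Patient-specific OLS of disability on time, time measured in
fractional days from the first visit converted at 365.25 days/year.
Residual SD is reported with the regression degrees of freedom.

**Eligibility.** ≥ 4 pre-therapy visits; every consecutive gap ≥ 6 calendar
months; total span ≥ 18 calendar months; fitted baseline slope ≥ 0.5
units/year. Calendar-month arithmetic is used (not 30-day months) with a
7-day tolerance per comparison for scheduling jitter; the tolerance is
configurable. All failed reasons are listed; the check always returns a
decision rather than raising.

**Individual trigger.** Strict inequalities, reading "exceeds" literally:
therapy slope > 5 × baseline slope, or annualized therapy lesion rate > 3 ×
baseline lesion rate. A therapy slope of exactly 5× does not trigger. The
criterion is undefined for non-positive baseline slopes — eligibility
guarantees positivity, and the code raises if handed such a patient. Lesion
"average" is annualized: counts recorded at visits after the first in a
window (each covering the interval since the previous visit), divided by
the window span in years. A per-scan alternative can be obtained by passing
raw counts. Therapy slopes need ≥ 2 on-therapy visits (configurable);
patients with fewer are reported as unevaluable, not as non-triggers.

**Arm rule and comparisons.** An arm stops when ≥ 3 patients trigger. The
2×2 trigger table is tested with a Pearson χ² with Yates continuity
correction (df = 1, two-sided), implemented with the clamped correction
`min(0.5, |O − E|)` so that tables within half a unit of expectation give
exactly zero — the textbook convention, and the one under which the
corrected and closed-form statistics agree identically. The uncorrected
statistic and p are always reported alongside: on sparse tables such as
3/9 vs 0/63 the two differ by an order of magnitude (p ≈ 1.5 × 10⁻⁴
corrected vs ≈ 3 × 10⁻⁶ uncorrected), and which is "the" χ² is a
convention, not a fact. A zero trigger column (identical proportions)
yields χ² = 0, p = 1; an empty arm is an error. Therapy-induced slope
changes (therapy − baseline per patient) are compared across arms with a
two-sided Wilcoxon rank-sum test, exact when the combined sample is ≤ 20
and untied.

## Transcriptional pathway activation score (tPPAS)

**Nucleus QC.** Exclusion iff mitochondrial fraction > 0.10 or UMI count
> 10,000, both strict, so a nucleus exactly at a threshold is kept. A
nucleus missing either statistic is reported unevaluable rather than
silently kept.

**Summaries.** AGE is the arithmetic mean of expression over the cells of a
type (computed on the values as provided — counts or normalized; the
package does not itself log-transform stored expression), and x is the
fraction of those cells with expression > 0. Sparse and dense inputs give
identical results; duplicating every cell changes nothing.

**Directionality.** d(g) ∈ {+1, −1}: knowledge-base annotation wins when
present; otherwise the sign of the analogous CSF protein's severity
correlation. A gene with neither source is dropped with a warning — a sign
is never guessed. Matching is case-insensitive.

**Outlier exclusion.** Per (group, cell type) independently, a single-pass
OLS of `log2(1 + AGE)` on x over the pathway genes; genes with residuals
strictly beyond ±2 residual SD (sample SD, ddof = 1) are excluded and the
fit is *not* re-run. A residual exactly at 2 SD is retained. If every gene
has the same detection fraction the regression is degenerate; the exclusion
falls back to outliers of `log2(1 + AGE)` alone and the result is flagged.
An essentially perfect fit (residual SD at float round-off) excludes
nothing.

**Score.** `tPPAS = Σ d(g) · AGE(g)` over the retained pathway genes — the
minimal formula consistent with its ingredient list (average gene
expression, directionality, the pathway gene set). This signed, unweighted
sum is the module's central interpretive decision; a hook to weight each
term by the fraction expressing exists (`weight_by_fraction=True`) but is
off by default, and the score is not normalized by gene count, so scores
are comparable across groups for the same retained gene set but not across
pathways of different size. Percent contrasts between groups are
`100 · (MS − control) / control`, reported to the nearest percent.

## Synthetic-data generator

One global seed drives independent named substreams per dataset, so a fixed
seed and configuration give bitwise-identical outputs across runs.

*Proteomics.* Abundances are log-normal (positive and right-skewed, like
RFU data, which exercises the heteroskedasticity the HD scaling must
absorb): per-protein baseline log-level ~ N(7, 1), residual log-SD 1.0.
MS patients carry a latent severity scalar (RRMS ~ N(δ, 1), progressive
~ N(2δ, 1) with δ the configured group shift; healthy donors sit at 0), and
the three observed severity outcomes are independent noisy monotone
transforms of it — the minimal generative structure under which a composite
"global severity" is meaningful. The informative pathway proteins add
β · severity to their log-level with the sign of their configured
directionality (β defaults to 0.4; recovery experiments use β = 1).
Optional paired on-therapy samples add a directionality-signed treatment
shift (0 by default, i.e. a null change analysis).

*Trajectories.* Defaults mirror a progressive-MS monitoring setting:
baseline slope ~ N(1.0, 0.3) disability units/year against an eligibility
floor of 0.5, visits every 183 days (4 pre-therapy, 3 on-therapy), visit
noise SD 1.0 units, therapy slope = multiplier × baseline slope with
disability continuous at therapy start. Lesion counts are Poisson with an
annualized rate and a therapy multiplier; the default rate is 0/year,
reflecting a population progressing by non-lesional activity — this also
keeps the null operating characteristics clean (with a positive Poisson
rate, lesion-criterion false triggers would persist in the noiseless
limit). Nonzero rates are exercised explicitly in tests.

*Expression summaries.* Per (group, cell type, gene): detection fraction
x ~ U(0.05, 0.95) and `log2(1 + AGE) = 0.3 + 3x + ε`, ε ~ N(0, 0.15).
Planted activation adds offset · d(g) to the MS group in configured cell
types (default 0.5 in microglia/macrophages and oligodendrocytes) —
uniform over the pathway, so it shifts the score, not the outlier
residuals. Planted outlier genes receive a residual displacement of 10
noise-SDs, alternating sign. A small cells × genes Poisson count matrix
with QC statistics exists solely to exercise the summarization and QC
paths.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: assay plate/batch structure and calibration
drift, missingness, correlated protein modules, informative visit
scheduling (dropout, therapy switches mid-window), lesion-count
overdispersion, cell-type misclassification, and ambient RNA. The
generator validates the pipeline's logic and calibration, not its field
performance.

## Problem sizes used in the shipped checks

The test suite and acceptance script run cohorts of up to 49 HD + 200 MS
samples on a 7,000-protein panel, 100-seed replicates of the 9-pair null
change analysis, 1,000-patient trajectory batches for trigger operating
characteristics, and exhaustive 2×2 tables with arm sizes ≤ 20 for the χ²
oracle check — sizes chosen to match the study setting where it matters
(pairs, panel width, arm sizes) while keeping a full run in tens of
seconds.

## Known limitations

- The published 10-protein score panel is not bundled; the frozen-weights
  JSON interface applies it verbatim once its identities and coefficients
  are supplied.
- Severity outcome models (CombiWISE, MS-DSS, brain-damage severity) are
  consumed as inputs, never derived.
- Whether the original selection used raw or FDR-adjusted p-values is not
  documented; raw p < α is the default here, with BH as an option.
- The tPPAS signed sum is an interpretation of the score's stated
  ingredients, documented above as a design decision rather than asserted
  as the original implementation's literal formula.
- Clustering, embedding, cell-type annotation, enrichment analysis and
  sequencing preprocessing are out of scope; the pipeline consumes labels
  and summaries and exports gene lists.
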