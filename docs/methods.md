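# Methods

`cystivar` implements a genotype-to-phenotype severity analysis for
cystinuria, an autosomal disorder of renal dibasic amino acid transport
caused by mutations in *SLC3A1* (encoding the rBAT heavy subunit) and
*SLC7A9* (encoding the b(0+)AT light subunit).  The analysis takes
protein-level mutation catalogues annotated with variant-effect-predictor
scores and clinical cohorts with per-allele genotypes, and asks whether a
simple two-level severity classification of mutations propagates to
measurable differences in patient phenotype.

## Mutation severity model

Each missense mutation is classified as **mild (1)** or **severe (2)** from
a single predictor's score.  Six predictors are supported, each with its
published deleterious threshold and a more stringent severe threshold:

| method            | direction  | deleterious | severe (score 2) |
|-------------------|------------|-------------|------------------|
| SIFT              | lower bad  | < 0.05      | ≤ 0.025          |
| PolyPhen2         | higher bad | ≥ 0.5       | ≥ 0.80           |
| MutationAssessor  | higher bad | > 1.9       | ≥ 2.7            |
| FATHMM            | lower bad  | ≤ −1.5      | < −8.5           |
| Condel            | higher bad | > 0.522     | > 0.672          |
| CADD              | higher bad | ≥ 15        | ≥ 27.5           |

Boundary strictness is method-specific and encoded literally (e.g. a SIFT
score of exactly 0.025 is severe; a FATHMM score of exactly −8.5 is mild).
Scores on the tolerated side of the deleterious threshold still map to
severity 1 — the mild band is unbounded on the tolerated side — with a
logged warning, since such mutations are predicted neutral.  Frameshift,
deletion, splice-site and nonsense mutations bypass the predictors and are
always severity 2, reflecting their typically drastic effect on the
protein.

### Threshold stabilisation

The severe thresholds are not taken on faith: `threshold_scan` re-scores
the whole cohort at each point of a stringency-ordered candidate grid and
`select_stable_threshold` returns the most stringent point of the longest
run of grid points over which the full patient-to-group assignment is
unchanged (ties go to the more stringent run; a minimum run length of 3
grid points is required, else the function advises a finer grid).
Judging stability on the full assignment rather than group sizes is a
deliberate choice: it is unambiguous and implies size stability.  Default
grid steps are 0.05 for probability-scaled methods (SIFT, PolyPhen2,
Condel), 0.5 for MutationAssessor and FATHMM, and 2.5 for CADD; these are
explicit package choices, as is the run-length criterion.

## Patient scoring

*SLC7A9* cystinuria is autosomal dominant with incomplete penetrance, so a
patient's score is the **sum** of per-allele severities, giving the range
1–4 (one mild mutation) … (two severe mutations, one per allele).
*SLC3A1* disease is autosomal recessive — both alleles must be mutated —
and the allele carrying the worse mutation is assumed not to be expressed,
so the patient score is the **minimum** of the two allele severities
(range 1–2).  A dominant allele carrying several mutations (not observed in
practice) is scored by its worst mutation, preserving the 1–4 range.  The
model deliberately treats two mild mutations the same as one severe
mutation (both sum to 2); this acknowledged simplification is part of the
scoring scheme, not something the implementation "fixes".  Patients with
no identified mutation are excluded with a notice; a patient with
mutations in both genes is excluded at table-reading time because the
scoring model does not cover mixed-gene genotypes; an *SLC3A1* patient
with a single mutated allele is inconsistent with recessive disease and is
excluded (optionally a hard error).

## Statistics

All comparisons use a two-sided Wilcoxon rank-sum test implemented in the
package.  The two-sided p-value is defined as the total null probability
of rank sums at least as far from the null mean as the observed one — the
exact-distribution convention, not a doubled one-sided tail; the
convention is stated because implementations differ.  Exact mode computes
the permutation distribution of the first sample's rank sum by dynamic
programming over the observed mid-ranks (scaled by two so they are
integers), equivalent to enumerating all C(n1+n2, n1) assignments of the
observed value multiset; the tail comparison is carried out in exact
integer arithmetic.  The normal approximation applies the standard tie
correction to the variance and a 0.5 continuity correction.  `auto` mode
uses the exact distribution when the pooled size is at most 20.

Multiple testing uses Bonferroni only: adjusted p = min(1, m·p), with the
family `m` defaulting to all group-pair × phenotype tests performed in one
analysis run, overridable.  The frequency/conservation relationship is
summarised with Spearman rank correlation (mid-ranks for ties, t-based
p-value); rank correlation is the natural choice for the integer
conservation scale.

## Group comparison design

Patients are partitioned by score; every unordered pair of groups with at
least `min_n` = 2 patients is compared on every phenotype (urinary
cystine, ornithine, arginine and lysine levels as supplied — no creatinine
normalisation is applied — age at presentation in years, and counts of
stone episodes and interventions over three years).  Null phenotype values
are dropped pairwise.  Summaries report n, mean, SD and median per group
and phenotype; both mean and median are emitted because "average" is
ambiguous, and SD is the reported dispersion (recorded in the output
metadata).

## Variant-set contrasts

Disease-associated and population-only variant sets are contrasted on
allele frequency, ConSurf conservation grade (1–9, 9 most conserved) and
predicted stability change ΔΔG (kcal/mol, negative destabilising).
A frequency of exactly 0 means "absent from the population panel" and is
kept as a literal zero value with its own histogram bin, not treated as
missing.  ConSurf histograms use one bin per grade; frequency histograms
use a zero bin plus decade-spaced bins; ΔΔG uses fixed 0.5 kcal/mol bins
shared between the two sets.  Bin edges are configurable.  Sequence
clustering reports maximal runs of mutated positions whose consecutive
gaps are at most `max_gap` (default 1, i.e. strictly adjacent residues).

## Synthetic data

The generator produces the study conditions the pipeline assumes, so every
stage is testable without clinical or population downloads:

* **Variant sets** — 94 *SLC3A1* and 58 *SLC7A9* disease-associated
  missense variants vs 318 and 144 population-only variants.  Disease
  variants: ConSurf weights placing 80% of mass on grades 6–9, allele
  frequency 0 with probability 0.5 and otherwise log-uniform between 1e−6
  and 1e−4, ΔΔG ~ Normal(−1.1, 0.8).  Population variants: 40% of ConSurf
  mass on 6–9 with a large spike at grade 1, frequencies log-uniform up to
  1e−2, ΔΔG ~ Normal(−0.65, 0.8).
* **Predictor emissions** — each disease variant carries a latent true
  severity (mild/severe with equal probability) and per-method scores are
  drawn from severity-conditional normals on the method's native scale and
  direction, clipped to valid ranges.  Mild means sit in the
  deleterious-but-mild band and severe means clearly beyond the severe
  threshold; SDs give roughly 2–6% per-method misclassification, so
  single-method severity recovery is ≥ 90% at n = 500.  A `noiseless()`
  configuration sets the SDs to zero for oracle checks.  Population
  variants reuse the mild emission; their predictor scores are not
  consumed by any analysis stage.
* **Cohort** — 41 recessive patients with exactly one mutation per allele
  and 32 dominant patients with one mutated allele with probability 0.4,
  two otherwise; each patient's latent score applies the aggregation rules
  to the latent severities of the sampled variants.  For power studies the
  config can instead request exact per-score group sizes for the dominant
  gene (`dominant_group_sizes`), since a random 32-patient cohort cannot
  realise balanced 40-patient groups.
* **Phenotypes** — urinary levels are log-normal (baseline medians 400,
  150, 100, 700 for cystine, ornithine, arginine, lysine; σ_log = 0.5)
  with a multiplicative shift per severity unit above the minimum score
  (1.10, 1.20, 1.40, 1.20 respectively); age at presentation is
  Normal(28 − 2.5·units, 8) truncated at 0.5 years; stone episodes and
  interventions are Poisson with baseline rates 2.0 and 1.0 and a 1.2×
  rate factor per unit.  Arginine carries the largest effect, matching the
  qualitative observation that urinary arginine separates severity groups
  most clearly, while the age and count effects are mild and often
  non-significant at cohort scale.  The effect sizes were fixed by power
  calibration of the generator's own design targets: with 40 patients per
  dominant group, the top-vs-bottom arginine comparison is
  Bonferroni-significant in well over 80% of seeded runs and attains the
  smallest adjusted p among all comparisons in ≥ 90% of runs.

One RNG stream per logical component (variants, predictor scores, cohort)
is spawned from the master seed, so enlarging the cohort does not perturb
the variant draws, and identical (config, seed) pairs reproduce tables
bit-identically.

### What the generator does not emulate

Real predictor scores are correlated across methods through shared
features; the generator draws them independently given the latent
severity, so cross-method agreement statistics are not faithful.  Latent
"true severity" is a modelling fiction — real mutations lie on a
continuum.  Population structure, linkage, genotyping error, ascertainment
bias and incomplete penetrance of the dominant gene are all absent.
Because noisy emissions are continuous and unimodal per class, the
threshold-stabilisation scan typically finds no stable run on default
noisy data (scores densely cover the grid); stable bands appear exactly
when the cohort's score distribution has a gap, as real cohorts showed.
Passing tests therefore demonstrate the pipeline's correctness and power
under the stated model, not the clinical effect sizes of any real cohort.

## Numerical choices and degenerate inputs

* Exact rank-sum tail membership is decided in integer arithmetic; the
  dynamic-programming counts are exact in float64 for pooled sizes ≤ 60.
* p-values are floored at the smallest positive float so that downstream
  log-scale handling is safe.
* Identical samples give p = 1; a zero-variance pooled sample in the
  approximation returns p = 1.
* Spearman correlation on constant input is flagged degenerate (NaN) not
  raised, so screening loops can proceed.
* Single-patient groups report a null SD; groups below the minimum size
  stay in the partition but are excluded from testing.
* Table writers are atomic (write-then-rename), outputs are UTF-8 TSV with
  Unix newlines and empty-string nulls, making byte-identity a testable
  contract.

## Problem sizes used in the checks

The shipped checks run the generator at its default scale (614 variants,
73 patients), with balanced 40-per-group dominant cohorts (160 patients)
for the power studies, 200 seeded replicates for the detection-rate
estimates, 2000 null draws for the size calibration of the exact test, and
exhaustive enumeration of all rank configurations up to pooled size 8 for
oracle agreement.  These sizes make the full suite complete in a few
minutes on one CPU while keeping Monte-Carlo error small relative to the
asserted margins.

## Known limitations

The severity model inherits the acknowledged crudeness of two-level
mutation scoring and additive patient scoring.  The published clinical
cohort (74 UK patients) and the population-panel extracts behind the
original analysis are not public, so the package reproduces the printed,
fully recomputable quantities and validates the statistical machinery on
synthetic cohorts; clinical p-values from that cohort are context, not
test targets.  Running the predictors themselves (SIFT, PolyPhen2,
MutationAssessor, FATHMM, Condel, CADD, ConSurf, mCSM) is out of scope:
their outputs are inputs to this pipeline.
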