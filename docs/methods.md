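# Methods

This note records the models, defaults and numerical choices behind
`methmark`, and what the synthetic validation does and does not show.

## Study design being modelled

The package implements the two-arm tissue-biomarker design common in
cancer epigenomics: (i) a discovery arm on array-style beta-value
matrices (CpG sites × samples, methylation fractions in [0, 1]) over
tumor, adenoma and para-tumor (adjacent normal, ≥ 5 cm from the tumor)
groups, with whole-blood / PBMC / PBL references; (ii) a replication
arm on targeted bisulfite-sequencing counts from paired tumor /
para-tumor tissue, with per-tumor KRAS mutation status.

## Region construction

CpG sites are ordered by (chromosome, position), 1-based inclusive.
A methylation region is a containment-maximal window of consecutive
sites with at least `min_sites = 6` members and span
`end − start < max_span = 1000` bp. The 1 kb bound reflects the decay
of methylation linkage beyond ~1,000 bp; 6 sites keeps region means
stable against single-probe noise. Construction is a two-pointer sweep:
for each left index the right pointer advances to the furthest site
within the span bound, and a window is emitted iff its right edge
advanced past the previous emission (equivalently: neither one-step
extension qualifies, which the test suite checks against an O(n²)
enumeration oracle). Non-maximal windows are redundant for region-level
means, hence excluded. Window semantics, and the decision to measure
the span as last − first with a strict bound, are package decisions;
only the 6-site / 1 kb numbers are fixed by the design.

## The DMR cascade

Per region and sample, methylation is the unweighted mean over
non-missing member sites; a sample with no observed member sites is
missing (no imputation). Group means McaM / MadM / McoM average these
per-sample values. The cascade:

1. **Differential test** — two-sided Wilcoxon rank-sum, tumors vs
   para-tumors: exact enumeration when the combined n ≤ 12 without
   ties, otherwise the normal approximation with tie and continuity
   corrections; BH step-up FDR across all regions.
2. **Thresholds** — McaM > 0.50, MadM > 0.50, McoM < 0.30, strict, as
   printed. Without adenoma samples MadM is undefined and the flag
   cannot be set.
3. **Blood filter** — region mean < 0.10 in each blood compartment.
   The source phrasing ("WB, PBMC, or PBL") is ambiguous between a
   conjunction and a disjunction; the default is the conjunction,
   consistent with the filter's purpose (markers must be near-silent
   in circulating blood DNA); `blood_mode="any"` gives the disjunctive
   reading.
4. **Per-gene selection** — minimum FDR per gene; ties broken by
   larger McaM − McoM, then leftmost coordinate (documented,
   deterministic). Unlabelled regions are kept as singletons.
5. **Expression filter** — Spearman correlation between region
   methylation and own-gene expression over paired samples, one-sided
   toward negative correlation, BH-adjusted p < 0.05. The original
   workflow couples this with transcription-factor-binding-site
   annotation against external databases; that annotation is out of
   scope here and the correlation clause stands alone. Spearman (not
   Pearson) is a package choice — robust to the bounded, non-normal
   beta scale. The one-sided p makes the filter's null pass rate equal
   the nominal level, which the suite verifies by simulation.

Filters set per-record flags and are applied in order, so flag
patterns are monotone in the cascade output.

## Targeted-sequencing QC

Conversion rate is estimated as converted / total non-CpG cytosines
per sample (the minimal sufficient statistic once alignment is
upstream). Samples drop when conversion < 0.98 (strict) or when > 30%
of sites have zero coverage; sites (over retained samples only, so an
excluded sample cannot penalise a site) keep when mean coverage > 20×
(strict) and the zero-coverage fraction is ≤ 20%. The printed rule for
site missingness is "< 20%"; the keep boundary is implemented as
≤ 0.20 and is configurable. QC is sample-then-site and idempotent:
re-running it on its own output changes nothing.

## Diagnostics

The per-region score is the per-sample region methylation itself (the
univariate logistic model is monotone in it, so cutoffs live on the
interpretable methylation scale). Components:

- **Logistic OR** — native IRLS (Newton–Raphson on the weighted normal
  equations, ridge 1e−9 for degenerate designs, tolerance 1e−10, max
  100 iterations). Complete separation is detected (fitted
  probabilities at their labels with diverging coefficients) and
  reported as an infinite-OR sentinel with a note, never an exception.
  The OR is reported per 0.1 increase in methylation fraction by
  default (`reporting_scale`); per-unit ORs on a [0, 1] predictor are
  astronomically scaled and no published predictor scale exists to
  match, so no equivalence to any particular published OR column is
  claimed.
- **AUC** — Mann–Whitney form via midranks (ties count ½), identical
  to the trapezoidal ROC area.
- **Cutoff** — every distinct score is evaluated as a "positive if
  score ≥ t" threshold; the maximiser of sensitivity + specificity is
  returned, ties resolved toward higher specificity, then the lower
  cutoff (deterministic; specificity-favouring, appropriate for a
  diagnostic intended to confirm).
- **Strata** — tumors are split by KRAS status, median age (young ≤
  median), sex, stage (I/II vs III/IV) or location; every stratum is
  compared against all retained para-tumors, which carry no
  tumor-level covariates. The Wilcoxon p is BH-adjusted across the
  marker panel within each stratum.
- **Subgroup comparison** — a two-sided Fisher exact test on the
  (subgroup × correct/incorrect) table of predictions at the
  all-sample cutoff.

## Cross-validation harness

The protocol is a repeated stratified random 80/20 holdout (class
proportions preserved to within one sample), default 1,000 repeats,
with sensitivity/specificity/accuracy averaged over repeats for train
and test splits separately; splits are shared across classifiers
within a repeat, so comparisons are paired. The literature this design
comes from describes both "fivefold cross-validation" and the repeated
80/20 protocol; the repeated holdout is the operationally specified
one and is the default, with `kfold_cv` as the alternative mode.
Stratification is a package addition to avoid degenerate single-class
training splits at small n. Three classifiers are native (logistic via
the shared IRLS core, Gaussian naive Bayes, nearest centroid); others
bind through the registry contract and are not part of the validated
surface.

## Synthetic data generator

Beta values are drawn from Beta(mκ, (1−m)κ) with mean m and precision
κ — bounded and overdispersed like real methylation fractions.
Defaults (fixed at design time):

| parameter | default | rationale |
| --- | --- | --- |
| background / para-tumor mean | 0.06 (κ = 20) | typical low-methylation promoter CpGs |
| hypermethylated mean (tumor, adenoma) | 0.60 (κ = 10) | clears the 0.50 threshold the way validated markers do |
| blood mean | 0.05 | passes the < 0.10 leakage filter by design |
| planted regions | 20 × (8 sites / 400 bp) | valid MRs with margin |
| background CpGs | 5,000, clustered | clusters of 1–4 and 6–12 sites so true-negative windows exist |
| samples per tissue group | 100 | desk-scale analogue of the public discovery cohorts |
| KRAS+ fraction | 0.48 | replication cohorts run near 50/50 |
| KRAS− hypermethylated fraction | 0.65 | places KRAS− sensitivity in the observed 0.5–0.8 band |
| coverage | NB(mean 100, dispersion 5) | comfortably above the 20× QC bound |
| conversion | 0.99 | modern bisulfite kits exceed 99% |
| site missingness / sample dropout | 0.05 / 0.05 | exercises both QC rules |

Targeted counts layer on top: coverage ~ negative binomial, methylated
count ~ Binomial(coverage, p_obs) with p_obs = m + (1 − m)(1 − c) for
conversion efficiency c (unconverted unmethylated cytosines read as
methylated), and per-sample non-CpG (converted, total) counts for the
conversion estimate. KRAS+ tumors are always hypermethylated at panel
regions; KRAS− tumors are hypermethylated with probability 0.65, else
control-like. The two-component mixture is the simplest structure that
reproduces the observed pattern in which every tumor misclassified as
control is KRAS−; the generator follows the reading that KRAS+ tumors
are the epigenetically homogeneous subgroup.

**What the generator does not model:** probe cross-hybridisation,
batch effects, cell-type composition, spatial correlation of
methylation beyond region-level block structure, read-level data, or
age/sex/stage effects on methylation (those covariates are emitted but
carry no signal). Passing synthetic tests therefore demonstrates
correctness of the machinery and the qualitative subgroup behaviour,
not performance on real cohorts; published cohort-level AUC/OR values
are not targets of the synthetic validation.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run at the generator
defaults above: 10 seeded discovery cohorts for cascade recovery
(≥ 90% planted recovery, ≤ 5% background contamination), one targeted
cohort of 100 patients × 5 markers for the stratified diagnostics and
the KRAS misclassification test, window-oracle comparison on 200
random manifests of up to 500 sites, binormal AUC convergence at
20,000 per group, logistic recovery (β = 3, n = 2,000, 20 seeds), and
the Bayes-accuracy harness (two Gaussians, Φ(μ) = 0.90, n = 400, 200
repeats). These sizes were chosen as the smallest at which the checked
quantities are statistically stable.

## Known limitations

- The expression filter tests anticorrelation only; regulatory
  annotation (TFBS) is out of scope.
- Para-tumor tissue is treated as a clean control; field effects in
  adjacent-normal tissue are not modelled.
- The OR scale of published tables is unstated in the source
  literature; ORs here are comparable internally, not across reports.
- Array preprocessing (normalisation, detection p-values, masking of
  cross-reactive probes) is assumed done upstream of the beta matrix.
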