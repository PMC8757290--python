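# Methods

## The analysis in brief

`multiphewas` implements an age-stratified, multi-contrast phenome-wide
association (PheWAS) procedure for longitudinal diagnosis-code data,
aimed at phenotypes enriched specifically in females with autism
spectrum disorder (ASD). Diagnosis events carry ICD-9-CM billing codes;
these are rolled up to phecodes (PheWAS-catalog phenotype groups, each
with a human-readable name and a higher-level category). Patients are
partitioned into four groups — females/males with ASD (cases) and
females/males without (controls) — and three phenome-wide contrasts are
run per age bin:

1. females with ASD vs males with ASD,
2. females with ASD vs females without ASD,
3. females without ASD vs males without ASD (the *exclusion* contrast).

A phecode is retained in a bin when it is significant in both of the
first two contrasts and **not** significant in the third. The exclusion
contrast removes phenotypes that are simply more common in females in
the general population and therefore carry no information about ASD.

## Cohort definitions

A **case** must have an ASD ICD-9-CM code (299.00, 299.01, 299.80,
299.81, 299.90, 299.91 by default) on at least 3 distinct service
dates, a record span (last minus first diagnosis event) of at least 366
days, age at the first qualifying code within 0–18 completed years, and
at least one mapped phenotype besides ASD. A **control** never carries
an ASD code and meets the same span and age criteria. Patients with one
or two ASD-code occasions are neither: repeated coding is what makes a
billing code a credible diagnosis proxy for a chronic condition (a
single code may reflect testing or rule-out), and a patient with some
but sub-threshold ASD codes is ambiguous, so they are excluded rather
than treated as controls.

Occasions are *distinct service dates*, not claim lines — claims
routinely duplicate a code within one encounter. "At least 12 months of
records" is read strictly as span ≥ 366 days; both readings are
configurable (`min_case_occasions`, `min_span_days`).

## Age stratification and phenotype profiles

Default bins, in completed years, inclusive: 0–2 (infants), 3–5
(prepubertal), 6–11 (peripubertal), 12–18 (postpubertal). A patient
contributes to every bin their record touches.

Comorbid phenotypes obey the same 3-distinct-dates rule. Two scopes are
offered because the natural-language rule is ambiguous:

* `overall` (default): the threshold applies to the patient's whole
  record; the phecode is then marked present in every bin with at least
  one occurrence.
* `per_bin`: the threshold applies within each bin separately (strictly
  more conservative; every `per_bin` triple is also an `overall`
  triple).

Per-bin denominators are likewise under-determined by the prose rule:
the default counts a patient toward a bin when their record span
overlaps the bin's age window (`span_overlap`); `all` counts every
cohort member in every bin.

## Exact inference

Each (phecode, bin, contrast) gives a 2×2 table of carriers vs
non-carriers by group. Conditioning on both margins, the carrier count
in group 1 follows Fisher's noncentral hypergeometric distribution with
noncentrality ψ equal to the odds ratio. The module reports:

* **p-value**: two-sided Fisher exact — the sum of conditional outcome
  probabilities at most as large as the observed one, with a relative
  tie slack of 1e-7 (the convention of the dominant statistical
  software implementations);
* **OR**: the conditional MLE, i.e. the ψ solving E[A | margins, ψ] = a
  (the same estimator R's `fisher.test` prints — the sample
  cross-product ratio is available via `or_kind="sample"`);
* **95% CI**: exact bounds inverting the one-sided tails at 0.025 each
  (ψ_L with P(A ≥ a | ψ_L) = 0.025, ψ_U with P(A ≤ a | ψ_U) = 0.025).

At the boundary of the conditional support the OR is 0 or +∞ and the
corresponding CI bound is 0 or +∞; no continuity correction is applied,
since exact methods handle boundaries natively and a Haldane–Anscombe
0.5 would silently change reported estimates. A table with an empty row
or column margin is degenerate: p = 1, OR undefined, with a warning.

All computations run in log space over the conditional support
(root-finding by Brent's method on log ψ), so tables with counts in the
tens of thousands complete in milliseconds. `scipy`'s
`contingency.odds_ratio` implements the same estimator but needs ~0.3 s
per large table, which is prohibitive at phenome scale; it is kept as an
independent cross-check in the test suite, alongside a brute-force
enumeration oracle (`multiphewas.oracle`) that recomputes p in exact
rational arithmetic and the CMLE/CI by bisection over an explicitly
enumerated pmf. The two routes agree on every 2×2 table with margins
≤ 12 to ~1e-15 in p and ~1e-9 relative in OR and CI.

## Multiple testing and effect-size filter

Significance uses a Bonferroni-corrected threshold, strict inequality
p < α/m with α = 0.01. The denominator m defaults to the number of
phecodes actually tested within the age bin (`bonferroni_mode=
"per_bin"`); a global mode divides by the whole vocabulary instead. The
prose rule does not fix this choice; per-bin is the default because each
bin is a separate family of tests.

On top of significance, an effect-size filter OR > 1.5 keeps results
near clinical relevance; a sweep utility re-applies cutoffs 1.1…2.0 to
the stored results without re-running any test (counts are monotone
non-increasing in the cutoff). Direction matters: only enrichment in
females with ASD (OR above the cutoff) is retained; protective signals
are flagged in a separate column and never enter the main result. An
infinite OR (boundary table) passes the filter only when its finite
lower CI bound exceeds 1, so boundary tables are neither silently
dropped nor trivially admitted.

Phecodes mapped from the case-defining ICD-9 codes are suppressed from
every contrast — they are significant by construction.

The exclusion step is applied per age bin by default (all testing is
age-stratified, and a phenotype female-biased only in adolescence
should not erase an infant signal); `exclusion_mode="global"` removes a
phecode everywhere once the exclusion contrast flags it in any bin.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with a ground-truth manifest so every pipeline stage is testable
without access to any proprietary claims extract:

* four groups with configurable sizes; the default male fraction of
  cases is 0.8, matching the ~4:1 male:female ratio of large ASD
  cohorts. The default case prevalence (0.25) emulates a case-control
  sampled extract rather than population prevalence (<1%), which would
  waste nearly all compute on controls at desk scale;
* per-phecode, per-bin carrier draws at a baseline prevalence (default
  0.05), with planted effects expressed as odds multipliers:
  `asd_female` multiplies carrier odds in females with ASD,
  `female_general` in all females. Because effects are odds shifts, the
  expected 2×2 OR of every contrast is known analytically (the ratio of
  the groups' multipliers). A phecode planted with *both* kinds is
  significant in all three contrasts and must be removed specifically
  by the exclusion step — a pure `female_general` effect never reaches
  the intersection, since the ASD-female vs control-female contrast is
  null for it;
* carriers receive 3–5 distinct service dates inside the bin window;
  noise pairs (never carriers) receive 1–2 dates and must be filtered
  out by the occasion threshold; ~5% of patients get sub-year record
  spans and ~5% of cases only 1–2 ASD codes, exercising the exclusion
  rules.

Implementation choices worth knowing: birth dates are pinned to
January 1 and event dates expressed as (completed-years age,
day-of-year ≤ 364), so an event's age in completed years is exact by
construction; occasion dates draw their day within disjoint 50-day
slots per occasion index, guaranteeing distinct service dates without
rejection sampling (days 350–364 are therefore never used — a harmless
non-uniformity). A single seeded NumPy generator with a fixed draw
order makes output byte-identical across runs.

What the generator does **not** emulate: realistic billing-code
frequency distributions, correlation between phenotypes, coding
intensity varying with care utilisation, or dataset-overlap artifacts.
Passing recovery tests therefore demonstrate that the pipeline's
machinery is correct under its own assumptions, not that the published
effect estimates would replicate on real claims.

## Validation studies and problem sizes

Two canned experiments (`multiphewas.validation`) back the acceptance
checks, sized to run comfortably on one CPU:

* **planted recovery** — 20 000 patients per group (80 000 total), 100
  phecodes, baseline prevalence 0.05, planted OR 3, 20 replicates
  (~15–20 s each). Reported: sensitivity over (replicate × bin) pairs,
  the fraction of replicates in which the doubly-planted probe is kept
  out of the result, false retentions of null phecodes, and the mean
  estimated OR of the planted phecode in the widest bin.
* **null calibration** — no planted effects, 200 phecodes, 2 000 per
  group, 10 replicates. The arm size is the package's choice (the
  family-wise error rate being tested is essentially independent of n).

## Reference result tables

Two CSV transcriptions of published result tables ship with the package
(`multiphewas/data/`): a 47-row claims-cohort table (27 distinct
phenotypes across four age bins) and a 7-row pediatric-hospital
validation table. They are inputs for the reporting module's set
arithmetic — per-bin counts, cross-age overlaps, cross-dataset name
comparison (case-insensitive, whitespace-normalized exact match) — and
for demos; no analysis result in this package is derived from them. The
category column is this package's annotation from the phecode
definition file's higher-level categories. The raw per-phenotype 2×2
counts behind those tables live in a journal supplementary file that is
not redistributed here; the OR/CI recomputation path
(`reporting.recompute_from_counts`) is exercised on synthetic counts
instead.

## Known limitations

* ICD-9-CM only; no ICD-10 mapping or phecode hierarchy exclusion
  ranges.
* No covariate adjustment (exact 2×2 inference only, no logistic
  PheWAS), no mid-p or unconditional (Barnard) alternatives.
* Per-bin denominators and the occasion-scope rule are configurable
  precisely because the source conventions are under-specified; results
  can shift between those readings.
* The enumeration oracle is quadratic in the support and intended for
  totals below a few hundred.
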