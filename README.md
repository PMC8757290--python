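# multiphewas

Age-stratified, multi-contrast phenome-wide association (PheWAS)
analysis of longitudinal diagnosis-code data, built to find
comorbidities enriched **specifically in females with autism spectrum
disorder (ASD)** — and, more generally, phenotypes enriched in any
subgroup defined by a case/control status and a stratifying variable.

It is aimed at biomedical informaticians working with claims or EHR
extracts: flat CSV files of patients, dated ICD-9-CM diagnosis events,
and an ICD-9→phecode mapping.

## The method

Patients are split into four groups — females/males with ASD (cases:
an ASD ICD-9-CM code on ≥ 3 distinct dates, > 12 months of records,
ages 0–18, ≥ 1 comorbid phenotype) and females/males without (controls:
no ASD code ever, same span/age rules). Diagnosis codes are rolled up
to phecodes, a comorbid phenotype counting only when coded on ≥ 3
distinct dates. Within each age bin (0–2, 3–5, 6–11, 12–18 completed
years) and for every phecode, three Fisher exact contrasts are run on
the 2×2 carrier tables:

| contrast | question |
|---|---|
| ASD-F vs ASD-M | sex-biased among cases? |
| ASD-F vs non-ASD-F | disease-associated among females? |
| non-ASD-F vs non-ASD-M | sex-biased in the general population? |

Each test reports the conditional-MLE odds ratio (the ψ solving
E[A | margins, ψ] = a under the noncentral hypergeometric model), an
exact 95% CI by tail inversion, and the two-sided exact p. A phecode is
**retained** in a bin when it is significant in both of the first two
contrasts (Bonferroni p < 0.01/m, OR > 1.5) and *not* significant in
the third — the intersection-minus-exclusion that separates "female
with ASD" signals from plain female-biased phenotypes.

A synthetic claims generator with a ground-truth manifest makes every
stage testable without access to any proprietary data; see
`docs/methods.md` for the model, parameter semantics and limitations.

## Worked example

Generate a synthetic cohort with one planted ASD-female effect
(phecode 305, OR 4) and analyze it:

```bash
multiphewas synth --seed 3 --out-dir demo/data \
    --n-patients 3000 --n-phecodes 12 --case-prevalence 0.5 \
    --planted 305:4.0
multiphewas run \
    --patients demo/data/patients.csv \
    --events demo/data/events.csv \
    --phecode-map demo/data/phecode_map.csv \
    --out-dir demo/out
```

which prints

```
retained phenotypes: 1
outputs in demo/out
```

`demo/out/intersection_table.csv` holds one row per (age bin, retained
phecode) with both contrasts' OR and CI, sorted within each bin by the
female-vs-male OR in decreasing order; `run_summary.json` records the
cohort funnel (cases/controls/excluded with reasons) and per-contrast
test counts, and `heatmap_matrix.csv` / `heatmap.png` give the
phenotype × age-bin OR matrix with categories in consecutive rows. The
retained phenotype is exactly the planted one: its female-vs-male and
ASD-vs-non-ASD ORs are both near 4, while null phecodes fall to the
Bonferroni/OR filter and any generally-female-biased phecode would be
removed by the third contrast.

Summaries of the shipped reference result tables (see below):

```bash
$ multiphewas report --fixture claims
   0-2: 3 retained
   3-5: 9 retained
  6-11: 17 retained
 12-18: 18 retained
distinct phenotype codes: 27
shared across all populated bins: 0
recurring in >1 bin: 13
```

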