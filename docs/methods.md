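# Methods

This note documents the models, defaults and design choices behind
`ehraudit`, in the order the pipeline runs them.

## Generation protocol

The audit assumes the standard generation protocol for model-produced EHR
corpora: a bank of 10 prompt templates, each with a single `{disease}`
placeholder, instantiated over a registry of 20 diseases spanning five
categories (epidemics; chronic conditions; mental health disorders; rare
diseases; diseases associated with geographic or socioeconomic factors), for
200 distinct prompts and, at 100 generations per prompt, 1,000 records per
disease per model. `ehraudit` manages the bank and registry
(`ehraudit.prompts`) but never calls a model: corpora arrive as JSONL or
from the synthetic generator.

The shipped template wordings and the disease→category mapping are
*editorial defaults* — the protocol fixes the shape, not the wording — and
both load from plain-text files so users can substitute their own. Disease
lookup is case-insensitive; listing order is alphabetical for deterministic
output.

## Synthetic corpus generator

`ehraudit.corpus` emulates a model's output corpus as a three-stage
sampling process per record:

1. with probability `p_irrelevant` the record is an off-target narrative
   containing no demographic token (operationalising hallucinated or
   unusable output — the content of such records is unspecified upstream,
   so the generator renders disease-adjacent administrative text);
2. otherwise each attribute is omitted with probability `p_missing[attr]`;
3. when present, the category is drawn from `category_dist[attr]` — which
   may itself include a `not_available` share, so a printed generated
   distribution (e.g. lupus at 97.9% female / 0.5% male / 1.6% NA) can be
   replayed verbatim via `config_from_percentages` — and rendered through
   one of ≥3 surface phrasings per category ("Sex: Female", "a
   62-year-old woman", "female patient"), so extraction is exercised beyond
   a single keyword.

Defaults follow the protocol: `n_records=1000` per disease, prompt ids
cycling 1–10. One `numpy` Generator is seeded per corpus and draws are
consumed in record order, making output byte-identical for identical
`(config, seed)`.

The closed form for the fully-relevant fraction,

    P(full) = (1 − p_irrelevant) · ∏ₐ (1 − p_missing[a]) · (1 − dist[a][NA]),

is exposed as `expected_full_fraction` and anchors the parameter-recovery
tests: empirical EPS must land within 3 binomial standard errors of
100·P(full).

What the generator does *not* emulate: clinically coherent narratives,
age/comorbidity structure, correlated attribute missingness, negated or
ambiguous demographic mentions, and model-specific phrasing drift. Passing
tests therefore demonstrate that the *pipeline arithmetic* is correct under
known ground truth — not that the shipped extraction patterns achieve any
particular recall on real model output.

## Extraction and the completeness taxonomy

Patterns are word-bounded, case-insensitive regexes per (attribute,
category), tried in ascending priority; the first match assigns the
category. The default set is compiled from an editable synonym table
(`data/synonyms.csv`), which also handles race label normalisation
("African American" → Black, "Caucasian" → White). Matches for two or more
categories of one attribute raise a conflict flag; the default policy keeps
the highest-priority match, while `strict_conflicts=True` demotes the
attribute to `not_available` (manual adjudication of conflicts is out of
scope). Negation is not handled — a record saying "not Hispanic" extracts
as Hispanic — a deliberate, logged limitation of pattern-based extraction.

A record with no extractable attribute is *irrelevant*; with every schema
attribute extracted, *full*; otherwise *partial*. Defining "irrelevant" as
zero extractable attributes makes the three-way partition N = Nᵢ + Nₛ + Nₐ
computable from text alone, and it is asserted on every tally.

## Scores and bias statistics

EPS and EPSᵢ are computed in full precision and reported on the 0–100 scale
(display rounds to 2 decimals); EPS ≤ EPSᵢ ≤ 100 holds structurally. By
default scores aggregate over all diseases of a model; grouping keys are
caller-specified.

SPD design choices, each locked by a test:

- **Denominator.** `P_generated` includes `not_available` records (matching
  the published generated-distribution layouts, where 77.2% female with
  15.3% NA against an 89.3% baseline gives −12.1), while benchmarks cover
  only real categories and sum to 1. Hence the identity
  Σ_categories SPD = −(NA%), checked as an invariant.
- **Classification.** Strict `>` / `<` on the *unrounded* SPD at a ±10-point
  threshold (display rounds to 1 decimal, so a displayed "+10.0" can be a
  genuine flag at 10.06). Symmetric in sign by construction.
- **Chi-square.** Observed counts exclude `not_available`; expected counts
  are benchmark proportions rescaled to the observed non-reserved total;
  df = k − 1; no continuity correction; no multiple-testing adjustment
  across the disease × model grid (each test at its own α = .05). An
  expected cell of 0 is an error; expected cells < 5 set a validity-caveat
  flag. The p-value comes from `scipy.stats.chisquare`; the statistic is
  verified against a brute-force Σ(obs−exp)²/exp oracle to 1e-9 in tests,
  and its type-I error is calibrated by simulation (500 benchmark-faithful
  corpora at n = 1000 must reject within the 99% binomial band around 5%).
- **Aggregation.** Per-model SPD means over diseases use the arithmetic
  mean and the *population* standard deviation (divisor n) — the convention
  under which the shipped per-disease columns reproduce their published
  summary statistics (e.g. Black-group SD 27.16 for the largest model).
- **Polarization.** For one family and disease, models are ordered by
  parameter count; the polarized category is the one with maximal SPD in
  the largest model; the effect is *present* when that category's SPD is
  strictly larger in the largest model than in the smallest, *monotone*
  when it never decreases along the ordering. With two models the two
  notions coincide.

## Benchmark fixtures

Gender baselines cover the 17 diseases with published two-sex prevalence at
the published 1-decimal precision. Preeclampsia, prostate cancer and
sarcoidosis have no usable gender baseline (the first two are effectively
single-sex, which would force an expected count of zero), so the pipeline
skips those (disease, gender) groups and lists them in the run manifest.

Race baselines are *reconstructed*: Black and White proportions per disease
recover exactly (to printed precision) as generated-ratio minus SPD,
consistently across all seven published model columns; per-disease Hispanic
and Asian baselines are not published in recomputable form, so the shipped
fixture splits the remainder (100 − Black − White) between them in the
18.7 : 6.0 ratio of 2020 US census population shares. Rows carry source
tags (`printed_prevalence_table`, `reconstructed_ratio_minus_spd`,
`reconstructed_census_split`) and the file is user-replaceable; analyses of
Hispanic/Asian SPDs against the reconstructed split should be treated as
illustrative.

## Pipeline and reproducibility

`run_pipeline` is a pure function of (corpus, benchmark, config, model
metadata): stages run extract → tally → performance → bias → aggregate →
polarization, tables have stable column order and row sort, and a rerun is
byte-identical. Malformed corpus lines are skipped and counted (failure
above 1%); groups missing a benchmark are skipped and enumerated in the
manifest rather than aborting. The heatmap export is a plain disease ×
model SPD matrix per category, suitable for any plotting front end.

Problem sizes in the test suite and acceptance script (corpora of 400–1,000
records, 500 Monte-Carlo replicates, 1,000 random oracle tables) were
chosen so binomial error bounds at 3 standard errors are a few percentage
points — tight enough to catch arithmetic errors, while keeping the full
suite fast to run routinely.

## Known limitations

- Extraction recall on real model output is unknown; guarantees hold on
  the generator's canonical phrasings only.
- The generator is a test harness, not a behavioural model of any language
  model's output distribution.
- Chi-square handling of `not_available` (exclude and rescale) is one
  defensible choice among several; published analyses do not state theirs.
- Per-disease Hispanic/Asian baselines are reconstructed, not sourced.
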