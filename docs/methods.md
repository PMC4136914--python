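# Methods

This note documents the model, the reference data, the numerical choices and
the limits of what the tests demonstrate.

## Scope and model

The package implements a societal-perspective, prevalence-based (year 2010)
bottom-up cost-of-illness model for 19 brain-disorder diagnostic groups (10
mental, 9 neurological). Three cost categories are modelled: direct
healthcare (inpatient, outpatient, drugs, procedures/devices), direct
non-medical (informal care, adaptations, transportation) and indirect costs
(production losses valued by the human-capital approach). Intangible costs,
premature-mortality losses and costs of crime are out of scope, as are
top-down expenditure allocation, discounting and cost-effectiveness
measures.

The estimand per disorder is the average yearly per-patient cost in EUR at
2010 prices, split by category, and its product with the prevalent patient
count (societal cost, € million/year). Totals are additive by construction:
category → disorder → diagnostic group → grand total, all computed in full
precision and rounded only for display.

## Harmonization

Article amounts are stated in their original currency and costing year and
adjusted in a fixed order: (1) conversion to EUR at the annual nominal
exchange rate of the costing year, (2) inflation to 2010 with the Spanish
all-items consumer price index. Converting first keeps all inflation in one
national series; the alternative (source-country inflation, then a current
exchange rate) typically shifts non-EUR rows by a few percent and is not
implemented. Harmonization is idempotent and positively homogeneous, and
each harmonized record carries its exchange-rate and CPI factors as an audit
trail.

The bundled CPI fixture is an index series derived from the Spanish annual
all-items HICP inflation rates, 1999–2012, base 1999 = 100. Its implied
2005→2010 factor (1.1286) reproduces the study's pooled epilepsy indirect
cost to 0.05% and the psychotic-disorders healthcare mean to 0.01%, which is
the strongest available check that the original adjustment used this series.
Exchange rates are annual ECB averages (EUR per unit) for USD and GBP,
2001–2010.

## Pooling and imputation

Within a pooling cell (disorder, or subtype where configured, × category)
the estimate is the un-weighted arithmetic mean over articles reporting that
category. Reported zeros are evidence and enter the mean; a missing cell is
*absent*, never zero. Outlier-flagged rows never pool; incidence-based rows
are excluded by default (`include_incidence` switches them in — the source
evidence table prints both prevalence- and incidence-based variants for two
stroke articles without stating which entered the original model).

Missing cells follow the hierarchy **observed mean → European median →
zero**, with provenance recorded (`observed_mean`, `imputed_eu_median`,
`unavailable_zero`). Indirect costs of dementia and child/adolescent
disorders are `forced_zero`: their patients are assumed outside the working
population. Observed means are never overwritten; switching imputation off
can only lower totals.

Subtype-structured disorders (headache: migraine/tension-type/medication-
overuse/other; mood: unipolar/bipolar; anxiety: generalized-anxiety/rest;
neuromuscular: ALS/rest) pool per subtype, impute per subtype (subtype-level
median first, disorder-level as fallback) and combine as a weighted average.
Without configured weights, subtype rows pool like ordinary observations.

## Reference data reconstruction

The European median costs and the subtype prevalence weights that the
original study consumed (from the European 2010 evidence review) are not
published in it. The bundled fixtures therefore *reconstruct* effective
values from the study's printed disorder-level per-patient table:

* for disorders flagged as fully imputed, the printed cells **are** the
  European medians and are bundled as such
  (`eu_medians_synthetic.csv` — the suffix marks the file as a
  reconstruction, not the original source table);
* for composite disorders, the non-observed component is back-solved from
  the printed cell given the observed component and a fixed weight: the
  generalized-anxiety share of anxiety patients is set to 0.10 and the ALS
  share of neuromuscular patients to 0.10 (≈2,300 of 23,003 patients,
  consistent with ALS prevalence of ~5/100,000); the unipolar share of mood
  patients (0.8176) is solved from the healthcare column, the only mood
  category observed for both subtypes;
* the four headache subtype weights are least-squares calibrated on the
  printed healthcare/indirect/total cells; the optimum (0.319/0.207/0.127/
  0.347) reproduces the printed 233/0/168 €/patient split to <0.01 €.

`scripts/rebuild_reference_fixtures.py` regenerates these fixtures deterministically. The
consequence to keep in mind: for those reconstructed cells the pipeline
*re-derives* printed values rather than predicting them; the genuine
predictions are the disorders driven by national evidence (dementia,
epilepsy, headache's observed cells, mood's observed cells, multiple
sclerosis, Parkinson, psychotic, stroke).

## Societal scaling

Patient counts are direct prevalent counts (as bundled) or prevalence
proportion × population (default 46,000,000 inhabitants). Indirect costs
scale by `N_d × working_age_fraction` unless the contributing estimates were
stated as all-ages averages. The bundled prevalence fixture uses
working-age fraction 1.0 throughout because its counts already reflect the
age spans of the underlying epidemiological review (18+ for most disorders,
14–65 for addictive and anxiety disorders, 2–17 for child/adolescent
disorders, 65+ for dementia); the division of labour is: age restriction
lives in the patient counts, not in the fraction.

A note on the published per-inhabitant figure: the study prints 1,725 € per
inhabitant, but 83,749 € million / 46 million inhabitants = 1,821 €. The
package computes the ratio and does not target the printed value.

## Quality-restricted sensitivity analysis

Quality is a per-row input label (derived by human reviewers from a 5-item
appraisal questionnaire; `QualityItems` helps derive a label from item
answers, with a configurable cut-off, since no fixed rule exists). The
re-analysis reruns the full pipeline on high-quality rows with **cell-level
fallback**: a cell that loses all its evidence keeps its baseline value and
the disorder is flagged. This guarantees fully-imputed disorders are
unaffected and restriction never manufactures evidence. Deltas are computed
on unrounded values; the overall delta is exactly the sum of per-disorder
deltas.

## Monte Carlo simulation

Per pooling cell, between-study uncertainty is modelled as
Triangular(min, mode, max) over the harmonized article values with the
un-weighted mean as mode. Method descriptions of this design sometimes call
the central value the "median observation"; the explicit rule adopted here
is mode = mean, with `mode="median"` available as a switch. Cells with a
single article, an imputed median or a forced zero are degenerate point
masses, keeping simulated totals comparable with the deterministic table.
Draws are independent across cells and disorders; 1,000 iterations by
default; a seed is mandatory and makes results bit-identical across reruns.

Eligible disorders default to the seven with more than one included article
(dementia, epilepsy, headache, mood disorders, multiple sclerosis,
Parkinson's disease, stroke). Psychotic disorders also have two articles
but only in a single category; they are excluded by default and can be added
via the `eligible` argument.

Summaries use empirical means and central quantiles with linear
interpolation between order statistics. The pooled statistic is the
per-iteration median of the eligible disorders' per-patient totals, its 90%
central interval, and the fraction of iterations exceeding a threshold
(default 3,000 €).

## Synthetic data generator

The generator emulates the structure of the evidence base: per disorder, a
configurable number of articles whose EUR-2010 category costs are drawn with
multiplicative log-normal noise parameterized by a coefficient of variation
(mean-preserving: the noise factor has expectation exactly 1, and CV = 0
reproduces the true means exactly); heterogeneous costing years and
currencies assigned from pools; per-category missingness; Bernoulli quality
labels. Amounts are written by *inverting* the harmonization maps (dividing
by the CPI factor and exchange rate the references will apply), so
harmonization recovers the drawn EUR-2010 values exactly and a zero-noise
corpus is a fixed point of the entire pipeline.

Defaults mirror the study conditions: 19 disorders with per-patient costs
spanning ~400 to ~37,000 €, sparse evidence (11 disorders with 1–8 articles,
8 with none), 40%/30% missingness for non-medical/indirect categories,
between-study CV 0.5 (the observed article scatter within multi-article
disorders is of this order), mostly-EUR currencies with a USD minority, and
prevalent patient counts spanning 21 thousand to 14 million.

What the generator does **not** emulate: correlated reporting across
categories within an article, severity-mix differences between study
samples, subtype structure (synthetic corpora are flat by default), or the
literature-screening process. Passing recovery tests therefore demonstrate
estimator correctness under independent, mean-preserving noise — not
robustness to the sampling biases real review corpora carry.

## Numerical choices

* Means and sums in double precision; no rounding before display.
* Patient counts from proportions round half-to-even to the nearest person.
* `numpy.random.default_rng(seed)` drives all sampling; disorders are
  simulated in a fixed order so results are reproducible given the seed.
* Triangular modes are clamped into [min, max] against floating-point drift.
* Quantiles: `numpy.quantile` linear interpolation.
* Empty category-value lists are errors for distribution fitting but legal
  (absent) for pooling.

## Verification strategy and known discrepancies

The test suite checks the pipeline bottom-up (unit oracles, property tests
with hypothesis, brute-force equivalence on tiny corpora, closed-form
triangular checks against scipy at 10⁵ draws / 3 SE, zero-noise exactness,
and 2-SE parameter recovery at CV 0.2 / 10 articles / 100 replicates) and
top-down against the published tables. Reproduction status:

* 17 of 19 published societal rows, the epilepsy/multiple-sclerosis/
  Parkinson per-patient rows, the per-disorder Monte Carlo means and
  intervals for epilepsy/headache/MS/Parkinson, and the sensitivity deltas
  for mood/MS/Parkinson reproduce within printed rounding or ~1%.
* **Stroke and dementia** pooled means cannot be derived from the published
  per-article amounts under any documented configuration (e.g. the stroke
  non-medical mean of 9,032 €/patient exceeds every average over the
  non-excluded articles; only an explicitly excluded outlier article could
  raise it that far). The full-pipeline grand total therefore lands 2.6%
  below the published 83,749 € million, and the corresponding acceptance
  test fails by design rather than masking the inconsistency.
* The published pooled-median exceedance probability (36.5% above 3,000 €)
  is inconsistent with the stated statistic: by the study's own 90%
  intervals, at least four of the seven simulated totals exceed 3,000 €
  almost surely, so the median of seven exceeds it with probability one.
  The faithful implementation reports ≈100% and the assertion fails openly.
* The published quality-restricted delta for dementia (+509 € million) has
  the opposite sign of what its three listed high-quality articles imply;
  only the overall and headache signs are asserted.

## Limitations

Comorbidity is ignored (patient counts sum across disorders, as in the
original design), article quality scoring is an input rather than a model,
no correlation structure is propagated through the Monte Carlo, and the
reconstructed European medians inherit any error in the printed
disorder-level table they were inverted from.
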