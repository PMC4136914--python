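# braincost

Prevalence-based cost-of-illness estimation for brain disorders, built as a
reusable, tested pipeline around the evidence base of a published Spanish
systematic review of brain-disorder cost studies (19 mental and neurological
diagnostic groups, costing year 2010).

## Who this is for

Health economists and epidemiologists who need to turn a heterogeneous set of
published per-patient cost estimates — different currencies, costing years,
cost categories and quality levels — into comparable per-patient and societal
cost tables with explicit, auditable assumptions, and to quantify how fragile
those tables are.

## The method

For each disorder *d* and cost category *c* ∈ {direct healthcare, direct
non-medical, indirect}:

1. **Harmonization.** Every article amount is converted to euros at the
   annual nominal exchange rate of its costing year, then inflated with the
   Spanish all-items CPI: `x_EUR2010 = x · fx(currency, year) ·
   CPI(2010)/CPI(year)`.
2. **Pooling.** The per-patient cost is the un-weighted arithmetic mean over
   the articles reporting that category,
   `p̂_dc = (1/n_dc) Σ_i x_idc`.
   Reported zeros count; unreported categories are skipped, not zero-filled.
3. **Imputation.** Categories with no national evidence take the pre-adjusted
   European median `m_dc`; categories with no European estimate either are
   zero; indirect costs are forced to zero for disorders whose patients are
   assumed outside the working population (dementia, child/adolescent
   disorders). Subtype-structured disorders (e.g. migraine vs tension-type
   headache) pool per subtype and combine with prevalence weights.
4. **Societal scaling.** `S_dc = p_dc · N_d / 10^6` (€ million), where `N_d`
   is the prevalent patient count; indirect costs scale only by the
   working-age share unless stated as an all-ages average. Roll-ups report
   mental/neurological/all totals and the cost-type distribution.
5. **Uncertainty.** (a) A quality-restricted re-analysis repeats everything
   using only high-quality articles, with cell-level fallback to baseline
   where restriction removes all evidence. (b) A Monte Carlo simulation
   draws per-patient totals from per-cell triangular distributions
   `Tri(min_i x_i, mean_i x_i, max_i x_i)` (degenerate for single-article
   cells), 1,000 iterations by default, fully seeded.

A synthetic-data generator produces corpora with known ground truth by
inverting the harmonization maps, so every pipeline stage is testable
end-to-end without any downloads.

## Worked example

The package ships the full evidence table (42 article × disorder rows) and
reference fixtures, used by default when no paths are configured:

```text
$ braincost estimate --out results
grand societal total: 81,558 EUR million

$ braincost simulate --seed 1 --out results
simulated 7 disorders, 1000 iterations; P(median > 3,000) = 1.000

$ braincost sensitivity --out results
overall delta: +3,792 EUR million (+4.6%)
```

`results/per_patient.csv` holds the pooled per-patient costs with provenance
tags (`observed_mean`, `imputed_eu_median`, `forced_zero`,
`unavailable_zero`), `results/societal.csv` the € million totals, and
`results/rollup.csv` group totals and cost-type shares. The grand total of
81,558 € million is the full-pipeline reconstruction of the study's 83,749
€ million (−2.6%; the residual is concentrated in the stroke and dementia
rows, whose published pooled means cannot be derived from the published
per-article amounts). The simulation table reproduces the published
per-disorder means and 90% intervals closely where the baseline agrees, e.g.

```text
disorder_id,disorder,mean,lower,upper
epilepsy,Epilepsy,7157.1,6525.8,7801.8
parkinsons_disease,Parkinson's disease,23085.9,22808.6,23364.5
```

The positive sensitivity delta says the quality-restricted evidence base
yields a *higher* total — the baseline is conservative.

Library use mirrors the CLI:

```python
from braincost import evidence_fixture, estimate, simulate

corpus, refs, configs = evidence_fixture()
bundle = estimate(corpus, refs, configs)
sim = simulate(bundle.harmonized, refs, configs, bundle.per_patient, seed=1)
print(bundle.per_patient["epilepsy"].total)   # 7178.3 EUR per patient-year
```

## Layout

| module | role |
|---|---|
| `braincost.corpus` | data model, corpus/reference I/O, validation reports |
| `braincost.harmonize` | currency conversion + CPI inflation |
| `braincost.aggregate` | pooling, imputation, subtype combination, societal scaling, roll-ups |
| `braincost.quality` | quality-restricted re-analysis |
| `braincost.montecarlo` | triangular-distribution Monte Carlo |
| `braincost.synthetic` | ground-truth generator + bundled evidence table |
| `braincost.cli` | `braincost estimate / simulate / sensitivity / synth` |

Methodological details, parameter choices and known limitations:
[`docs/methods.md`](docs/methods.md).
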