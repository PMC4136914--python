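"""Synthetic corpora with known ground truth, plus the bundled evidence table.

The generator emulates the statistical structure of a cost-of-illness
evidence base: per disorder, a handful of articles whose per-patient category
costs scatter around true EUR-2010 means with log-normal between-study noise,
stated in heterogeneous currencies and costing years, with structured
missingness and quality labels.  Amounts are written by applying the
*inverse* exchange-rate and CPI maps, so harmonization inverts the generation
exactly and a zero-noise corpus is a fixed point of the whole pipeline.

`evidence_fixture` returns the packaged evidence table of a Spanish
systematic review of brain-disorder cost studies (42 article x disorder
rows) together with the bundled reference tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

from .aggregate import (
    PerPatientCost,
    CategoryCost,
    OBSERVED,
    IMPUTED,
    FORCED_ZERO,
    UNAVAILABLE_ZERO,
    RollupSummary,
    SocietalCost,
    rollup,
    societal_cost,
)
from .corpus import (
    CostObservation,
    DisorderConfig,
    PrevalenceEntry,
    ReferenceSet,
    read_corpus,
    read_disorder_configs,
    read_references,
)
from .errors import ConfigurationError
from .vocab import CATEGORIES, DISORDER_IDS, group_of


@dataclass
class SyntheticDisorderSpec:
    """Generator parameters for one disorder.

    ``true_means`` are noise-free EUR-2010 per-patient category costs (omit a
    category to make it structurally unobserved); ``cv`` is the between-study
    coefficient of variation of the log-normal article noise;
    ``missing_prob`` is the chance an article fails to report a category.
    """

    true_means: dict[str, float]
    n_articles: int = 3
    cv: float = 0.5
    missing_prob: dict[str, float] = field(default_factory=dict)
    quality_high_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.n_articles < 0:
            raise ConfigurationError("n_articles must be >= 0")
        if self.cv < 0:
            raise ConfigurationError("cv must be >= 0")
        for c, m in self.true_means.items():
            if c not in CATEGORIES or m < 0:
                raise ConfigurationError(f"bad true mean {c}={m}")
        for c, p in self.missing_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"missing_prob[{c}] outside [0, 1]")


@dataclass
class SyntheticConfig:
    """Complete specification of a generation run."""

    disorders: dict[str, SyntheticDisorderSpec]
    years: tuple[int, ...] = (2004, 2006, 2008, 2010)
    currencies: tuple[str, ...] = ("EUR", "EUR", "EUR", "USD")  # mostly Euro
    cpi_base_year: int = 1999
    cpi_growth: float = 0.028  # yearly all-items inflation
    fx: dict[tuple[str, int], float] = field(default_factory=dict)
    eu_medians: dict[tuple[str, str | None, str], float] = field(default_factory=dict)
    prevalence: dict[str, int] = field(default_factory=dict)
    population: int = 46_000_000
    target_year: int = 2010

    def cpi_series(self) -> dict[int, float]:
        years = range(self.cpi_base_year, max(max(self.years), self.target_year) + 1)
        return {
            y: 100.0 * (1.0 + self.cpi_growth) ** (y - self.cpi_base_year)
            for y in years
        }


@dataclass(frozen=True)
class SyntheticTruth:
    """Noise-free expected pipeline outputs, computed analytically."""

    per_patient: dict[str, PerPatientCost]
    societal: dict[str, SocietalCost]
    summary: RollupSummary

    @property
    def grand_total(self) -> float:
        return self.summary.groups["all"].total


def default_config(cv: float = 0.5) -> SyntheticConfig:
    """Study-shaped defaults: 19 disorders spanning four orders of magnitude
    of per-patient cost, sparse evidence (several disorders with no articles,
    many categories unreported), mixed costing years and a minority non-EUR
    currency -- the situation the pooling and imputation rules exist for."""
    means = {
        "addiction": (1300.0, 900.0, 1300.0),
        "anxiety_disorders": (700.0, 30.0, 950.0),
        "child_adolescent_disorders": (400.0, 3000.0, 0.0),
        "eating_disorders": (360.0, 45.0, 90.0),
        "intellectual_disability": (6400.0, 3200.0, 0.0),
        "mood_disorders": (1500.0, 470.0, 1600.0),
        "personality_disorders": (700.0, 580.0, 4000.0),
        "psychotic_disorders": (5900.0, 0.0, 11700.0),
        "sleep_disorders": (400.0, 0.0, 280.0),
        "somatoform_disorders": (430.0, 0.0, 470.0),
        "brain_tumor": (12400.0, 0.0, 6800.0),
        "dementia": (5800.0, 19500.0, 0.0),
        "epilepsy": (4700.0, 620.0, 1800.0),
        "headache": (230.0, 0.0, 170.0),
        "multiple_sclerosis": (12300.0, 12500.0, 12200.0),
        "neuromuscular_disorders": (4600.0, 3200.0, 14200.0),
        "parkinsons_disease": (8600.0, 4900.0, 9600.0),
        "stroke": (3500.0, 9000.0, 840.0),
        "traumatic_brain_injury": (2400.0, 830.0, 4200.0),
    }
    # Evidence density mirrors a sparse review: a third of disorders have no
    # national article at all and rely entirely on European medians.
    n_articles = {
        "dementia": 8,
        "stroke": 5,
        "mood_disorders": 5,
        "multiple_sclerosis": 4,
        "headache": 3,
        "epilepsy": 2,
        "psychotic_disorders": 2,
        "parkinsons_disease": 2,
        "anxiety_disorders": 1,
        "neuromuscular_disorders": 1,
        "traumatic_brain_injury": 1,
    }
    disorders: dict[str, SyntheticDisorderSpec] = {}
    eu_medians: dict[tuple[str, str | None, str], float] = {}
    prevalence: dict[str, int] = {}
    rng_sizes = {  # prevalent patients, order of magnitude as in the field
        "headache": 14_000_000,
        "anxiety_disorders": 6_200_000,
        "sleep_disorders": 4_100_000,
        "mood_disorders": 3_000_000,
        "somatoform_disorders": 1_850_000,
        "addiction": 1_440_000,
        "stroke": 640_000,
        "dementia": 610_000,
        "child_adolescent_disorders": 480_000,
        "psychotic_disorders": 450_000,
        "personality_disorders": 400_000,
        "intellectual_disability": 380_000,
        "traumatic_brain_injury": 335_000,
        "epilepsy": 225_000,
        "eating_disorders": 130_000,
        "parkinsons_disease": 80_000,
        "multiple_sclerosis": 36_000,
        "neuromuscular_disorders": 23_000,
        "brain_tumor": 21_000,
    }
    for d in DISORDER_IDS:
        h, m, i = means[d]
        true_means = {"healthcare": h, "nonmedical": m, "indirect": i}
        disorders[d] = SyntheticDisorderSpec(
            true_means=true_means,
            n_articles=n_articles.get(d, 0),
            cv=cv,
            missing_prob={"nonmedical": 0.4, "indirect": 0.3},
            quality_high_prob=0.45,
        )
        for cat, v in true_means.items():
            eu_medians[(d, None, cat)] = v
        prevalence[d] = rng_sizes[d]
    return SyntheticConfig(
        disorders=disorders,
        fx={("USD", y): 0.8 for y in (2004, 2006, 2008, 2010)},
        eu_medians=eu_medians,
        prevalence=prevalence,
    )


def default_disorder_configs() -> dict[str, DisorderConfig]:
    forced = {"dementia", "child_adolescent_disorders"}
    return {
        d: DisorderConfig(d, group_of(d), indirect_forced_zero=d in forced)
        for d in DISORDER_IDS
    }


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative noise with mean exactly 1 and the given CV."""
    if cv == 0.0:
        return 1.0
    sigma2 = np.log1p(cv * cv)
    return float(np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2))))


def expected_truth(
    config: SyntheticConfig, configs: Mapping[str, DisorderConfig] | None = None
) -> SyntheticTruth:
    """Analytical noise-free expectations under the generator's parameters.

    A category's expected pooled value is its true mean when articles can
    report it, the European median when it is never observed, zero otherwise;
    forced-zero indirect cells are zero.  Satisfies the aggregation
    invariants by construction.
    """
    configs = configs or default_disorder_configs()
    per_patient: dict[str, PerPatientCost] = {}
    societal: dict[str, SocietalCost] = {}
    for d in DISORDER_IDS:
        spec = config.disorders[d]
        cells: dict[str, CategoryCost] = {}
        for cat in CATEGORIES:
            if cat == "indirect" and configs[d].indirect_forced_zero:
                cells[cat] = CategoryCost(0.0, FORCED_ZERO)
                continue
            observable = (
                spec.n_articles > 0
                and cat in spec.true_means
                and spec.missing_prob.get(cat, 0.0) < 1.0
            )
            if observable:
                cells[cat] = CategoryCost(spec.true_means[cat], OBSERVED)
            elif (d, None, cat) in config.eu_medians:
                cells[cat] = CategoryCost(config.eu_medians[(d, None, cat)], IMPUTED)
            else:
                cells[cat] = CategoryCost(0.0, UNAVAILABLE_ZERO)
        ppc = PerPatientCost(d, cells["healthcare"], cells["nonmedical"], cells["indirect"])
        per_patient[d] = ppc
        societal[d] = societal_cost(ppc, config.prevalence[d])
    return SyntheticTruth(per_patient, societal, rollup(societal))


def generate_corpus(
    config: SyntheticConfig, seed: int
) -> tuple[list[CostObservation], ReferenceSet, SyntheticTruth]:
    """Draw a corpus + consistent references + analytical ground truth.

    Article amounts are drawn in EUR at target-year prices around the true
    means, then *de-harmonized* into an assigned (currency, year) by dividing
    by the CPI factor and exchange rate the references will apply, so
    harmonization recovers the drawn EUR-2010 amounts exactly.
    """
    rng = np.random.default_rng(seed)
    cpi = config.cpi_series()
    observations: list[CostObservation] = []
    for d in sorted(config.disorders):
        spec = config.disorders[d]
        for k in range(spec.n_articles):
            year = int(rng.choice(config.years))
            currency = str(rng.choice(config.currencies))
            if currency != "EUR" and (currency, year) not in config.fx:
                currency = "EUR"
            fx_rate = 1.0 if currency == "EUR" else config.fx[(currency, year)]
            cpi_factor = cpi[config.target_year] / cpi[year]
            amounts: dict[str, float | None] = {}
            for cat in CATEGORIES:
                if cat not in spec.true_means:
                    amounts[cat] = None
                    continue
                if rng.random() < spec.missing_prob.get(cat, 0.0):
                    amounts[cat] = None
                    continue
                eur2010 = spec.true_means[cat] * _lognormal_factor(rng, spec.cv)
                amounts[cat] = eur2010 / (fx_rate * cpi_factor)
            if all(v is None for v in amounts.values()):
                # keep the record usable: always report the largest category
                cat = max(spec.true_means, key=spec.true_means.get)
                eur2010 = spec.true_means[cat] * _lognormal_factor(rng, spec.cv)
                amounts[cat] = eur2010 / (fx_rate * cpi_factor)
            observations.append(
                CostObservation(
                    study_id=f"synth_{d}_{k:02d}",
                    disorder_id=d,
                    subtype_id=None,
                    costing_year=year,
                    currency=currency,
                    cost_healthcare=amounts["healthcare"],
                    cost_nonmedical=amounts["nonmedical"],
                    cost_indirect=amounts["indirect"],
                    quality_high=bool(rng.random() < spec.quality_high_prob),
                )
            )
    refs = ReferenceSet(
        cpi=cpi,
        fx=dict(config.fx),
        eu_medians=dict(config.eu_medians),
        prevalence={
            d: PrevalenceEntry(disorder_id=d, n_patients=n)
            for d, n in config.prevalence.items()
        },
        population=config.population,
    )
    return observations, refs, expected_truth(config)


# ---------------------------------------------------------------------------
# bundled evidence table


def _data_path(name: str) -> Path:
    return Path(resources.files("braincost.data").joinpath(name))


def evidence_fixture() -> tuple[
    list[CostObservation], ReferenceSet, dict[str, DisorderConfig]
]:
    """The packaged Spanish evidence table (42 rows, exclusion/incidence flags
    per its footnotes) with bundled CPI, exchange-rate, European-median and
    prevalence references and per-disorder configuration."""
    corpus = read_corpus(_data_path("evidence_corpus.csv"))
    refs = read_references(
        {
            "cpi": _data_path("cpi_spain.csv"),
            "fx": _data_path("fx_ecb.csv"),
            "eu_medians": _data_path("eu_medians_synthetic.csv"),
            "prevalence": _data_path("prevalence.csv"),
        }
    )
    configs = read_disorder_configs(_data_path("disorders.csv"))
    return corpus, refs, configs


__all__ = [
    "SyntheticDisorderSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "default_config",
    "default_disorder_configs",
    "expected_truth",
    "generate_corpus",
    "evidence_fixture",
]
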