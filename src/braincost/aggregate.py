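"""Pool harmonized observations into per-patient and societal costs.

Pooling follows the bottom-up, prevalence-based recipe:

* per disorder (or subtype) and cost category, the un-weighted arithmetic
  mean over the articles that report the category (explicit zeros count,
  absences are skipped);
* categories with no evidence are imputed from pre-adjusted European median
  costs, and set to zero when no median exists either;
* indirect costs are forced to zero for disorders whose patients are assumed
  to be outside the working population;
* subtype-structured disorders combine subtype cells as a weighted average
  under configured prevalence weights (without weights, subtype rows pool
  like ordinary observations);
* societal cost = per-patient cost x number of prevalent patients, with
  indirect costs scaled by the working-age fraction unless the evidence was
  stated as an all-ages average.

Every cell carries a provenance tag so imputation is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .corpus import DisorderConfig, PrevalenceEntry, ReferenceSet
from .errors import CompletenessError, ConfigurationError
from .harmonize import HarmonizedObservation
from .vocab import CATEGORIES, DISORDER_IDS, MENTAL, NEUROLOGICAL, group_of

OBSERVED = "observed_mean"
IMPUTED = "imputed_eu_median"
FORCED_ZERO = "forced_zero"
UNAVAILABLE_ZERO = "unavailable_zero"


@dataclass(frozen=True)
class CategoryCost:
    amount: float
    provenance: str

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ConfigurationError(f"negative category cost {self.amount}")


@dataclass(frozen=True)
class PerPatientCost:
    """Pooled EUR per-patient yearly cost of one disorder, by category."""

    disorder_id: str
    healthcare: CategoryCost
    nonmedical: CategoryCost
    indirect: CategoryCost

    def category(self, cat: str) -> CategoryCost:
        return getattr(self, cat)

    @property
    def total(self) -> float:
        return self.healthcare.amount + self.nonmedical.amount + self.indirect.amount


@dataclass(frozen=True)
class SocietalCost:
    """Population-level cost of one disorder, EUR million per year."""

    disorder_id: str
    n_patients: int
    healthcare: float
    nonmedical: float
    indirect: float

    def category(self, cat: str) -> float:
        return getattr(self, cat)

    @property
    def total(self) -> float:
        return self.healthcare + self.nonmedical + self.indirect


@dataclass(frozen=True)
class GroupSummary:
    n_patients: int
    healthcare: float
    nonmedical: float
    indirect: float
    total: float
    mean_per_patient: float


@dataclass(frozen=True)
class RollupSummary:
    """Totals for the mental group, the neurological group and all disorders,
    plus the distribution of the societal cost over the three categories."""

    groups: dict[str, GroupSummary]
    shares: dict[str, float]  # category -> % of grand societal total
    group_shares: dict[str, dict[str, float]]
    cost_per_inhabitant: float | None = None  # EUR/inhabitant/year


# ---------------------------------------------------------------------------
# pooling


def included_observations(
    observations: Iterable[HarmonizedObservation], include_incidence: bool = False
) -> list[HarmonizedObservation]:
    """Drop outlier-excluded rows and (by default) incidence-based rows."""
    return [
        o
        for o in observations
        if not o.excluded_outlier and (include_incidence or o.basis == "prevalence")
    ]


def category_mean(
    observations: Iterable[HarmonizedObservation],
    disorder_id: str,
    category: str,
    subtype_id: str | None = ...,  # ... = any subtype
) -> float | None:
    """Un-weighted mean of a category over the rows that report it.

    Returns ``None`` when no included row reports the category.  Explicit
    zeros participate in the mean; the caller is expected to have filtered
    with :func:`included_observations`.
    """
    values = [
        v
        for o in observations
        if o.disorder_id == disorder_id
        and (subtype_id is ... or o.subtype_id == subtype_id)
        and (v := o.amount(category)) is not None
    ]
    if not values:
        return None
    return sum(values) / len(values)


def category_table(
    observations: Iterable[HarmonizedObservation],
    configs: Mapping[str, DisorderConfig],
    include_incidence: bool = False,
) -> dict[tuple[str, str | None], dict[str, float | None]]:
    """Observed category means per pooling cell.

    Cells are ``(disorder_id, subtype_id)``; disorders without configured
    subtype weights pool all their rows into a single ``(disorder, None)``
    cell, mirroring the un-weighted-mean rule.
    """
    obs = included_observations(observations, include_incidence)
    table: dict[tuple[str, str | None], dict[str, float | None]] = {}
    for d in DISORDER_IDS:
        weights = configs[d].subtype_weights if d in configs else None
        if weights:
            for s in weights:
                table[(d, s)] = {
                    c: category_mean(obs, d, c, subtype_id=s) for c in CATEGORIES
                }
        else:
            table[(d, None)] = {c: category_mean(obs, d, c) for c in CATEGORIES}
    return table


def impute_missing(
    table: Mapping[tuple[str, str | None], Mapping[str, float | None]],
    refs: ReferenceSet,
    configs: Mapping[str, DisorderConfig],
    imputation: bool = True,
) -> dict[tuple[str, str | None], dict[str, CategoryCost]]:
    """Complete every pooling cell with the imputation hierarchy.

    observed mean -> European median -> zero; indirect costs of
    force-zero disorders are zeroed regardless.  Observed means are never
    overwritten.  With ``imputation=False`` missing cells go straight to
    zero (``unavailable_zero``).
    """
    completed: dict[tuple[str, str | None], dict[str, CategoryCost]] = {}
    for (d, s), means in table.items():
        cfg = configs.get(d) or DisorderConfig(d, group_of(d))
        cell: dict[str, CategoryCost] = {}
        for cat in CATEGORIES:
            if cat == "indirect" and cfg.indirect_forced_zero:
                cell[cat] = CategoryCost(0.0, FORCED_ZERO)
                continue
            v = means.get(cat)
            if v is not None:
                cell[cat] = CategoryCost(v, OBSERVED)
                continue
            median = refs.eu_median(d, s, cat) if imputation else None
            if median is not None:
                cell[cat] = CategoryCost(median, IMPUTED)
            else:
                cell[cat] = CategoryCost(0.0, UNAVAILABLE_ZERO)
        completed[(d, s)] = cell
    return completed


def combine_subtypes(
    subtype_costs: Mapping[str, Mapping[str, CategoryCost]],
    weights: Mapping[str, float],
    disorder_id: str,
) -> PerPatientCost:
    """Weighted average of subtype cells into one disorder-level record.

    The disorder-level provenance of a category is ``observed_mean`` as soon
    as any subtype contributes evidence, ``imputed_eu_median`` when only
    medians contribute, and the common zero tag when every component is zero.
    """
    if set(weights) != set(subtype_costs):
        raise ConfigurationError(
            f"{disorder_id}: subtype weights {sorted(weights)} do not match "
            f"subtypes {sorted(subtype_costs)}"
        )
    cells: dict[str, CategoryCost] = {}
    for cat in CATEGORIES:
        amount = sum(w * subtype_costs[s][cat].amount for s, w in weights.items())
        provs = {subtype_costs[s][cat].provenance for s in weights}
        if OBSERVED in provs:
            prov = OBSERVED
        elif IMPUTED in provs:
            prov = IMPUTED
        elif provs == {FORCED_ZERO}:
            prov = FORCED_ZERO
        else:
            prov = UNAVAILABLE_ZERO
        cells[cat] = CategoryCost(amount, prov)
    return PerPatientCost(disorder_id, cells["healthcare"], cells["nonmedical"], cells["indirect"])


def per_patient_costs(
    observations: Iterable[HarmonizedObservation],
    refs: ReferenceSet,
    configs: Mapping[str, DisorderConfig],
    include_incidence: bool = False,
    imputation: bool = True,
) -> dict[str, PerPatientCost]:
    """Full pooling pipeline: category means, imputation, subtype combination."""
    table = category_table(observations, configs, include_incidence)
    completed = impute_missing(table, refs, configs, imputation)
    out: dict[str, PerPatientCost] = {}
    for d in DISORDER_IDS:
        weights = configs[d].subtype_weights if d in configs else None
        if weights:
            subtype_cells = {s: completed[(d, s)] for s in weights}
            out[d] = combine_subtypes(subtype_cells, weights, d)
        else:
            cell = completed[(d, None)]
            out[d] = PerPatientCost(d, cell["healthcare"], cell["nonmedical"], cell["indirect"])
    return out


# ---------------------------------------------------------------------------
# scaling to the population


def patient_count(entry: PrevalenceEntry, population: int) -> int:
    """Number of prevalent patients: a direct count, or proportion x population."""
    if entry.n_patients is not None:
        return entry.n_patients
    return round(entry.proportion * population)


def societal_cost(
    per_patient: PerPatientCost,
    n_patients: int,
    working_age_fraction: float = 1.0,
    indirect_basis: str = "working_age",
) -> SocietalCost:
    """Scale per-patient costs to the population, in EUR million.

    Indirect costs apply only to working-age patients unless the underlying
    estimates were an all-ages average.
    """
    if n_patients < 0:
        raise ConfigurationError("n_patients must be >= 0")
    indirect_n = n_patients if indirect_basis == "all_ages" else n_patients * working_age_fraction
    return SocietalCost(
        disorder_id=per_patient.disorder_id,
        n_patients=n_patients,
        healthcare=per_patient.healthcare.amount * n_patients / 1e6,
        nonmedical=per_patient.nonmedical.amount * n_patients / 1e6,
        indirect=per_patient.indirect.amount * indirect_n / 1e6,
    )


def disorder_indirect_basis(
    observations: Iterable[HarmonizedObservation], disorder_id: str
) -> str:
    """Effective indirect-cost basis for a disorder: ``all_ages`` when any
    contributing indirect estimate was stated as an all-ages average."""
    for o in observations:
        if (
            o.disorder_id == disorder_id
            and o.cost_indirect is not None
            and o.indirect_basis == "all_ages"
        ):
            return "all_ages"
    return "working_age"


def societal_costs(
    per_patient: Mapping[str, PerPatientCost],
    refs: ReferenceSet,
    observations: Iterable[HarmonizedObservation] = (),
) -> dict[str, SocietalCost]:
    observations = list(observations)
    out: dict[str, SocietalCost] = {}
    for d, ppc in per_patient.items():
        entry = refs.prevalence[d]
        out[d] = societal_cost(
            ppc,
            patient_count(entry, refs.population),
            working_age_fraction=entry.working_age_fraction,
            indirect_basis=disorder_indirect_basis(observations, d),
        )
    return out


# ---------------------------------------------------------------------------
# roll-up


def _group_summary(socs: Sequence[SocietalCost]) -> GroupSummary:
    n = sum(s.n_patients for s in socs)
    h = sum(s.healthcare for s in socs)
    m = sum(s.nonmedical for s in socs)
    i = sum(s.indirect for s in socs)
    total = h + m + i
    return GroupSummary(
        n_patients=n,
        healthcare=h,
        nonmedical=m,
        indirect=i,
        total=total,
        mean_per_patient=total * 1e6 / n if n else 0.0,
    )


def rollup(
    societal: Mapping[str, SocietalCost],
    configs: Mapping[str, DisorderConfig] | None = None,
    population: int | None = None,
) -> RollupSummary:
    """Group totals (mental / neurological / all) and cost-type shares.

    Requires all 19 disorders; shares are computed on unrounded values and
    sum to 100% exactly (up to floating-point error).
    """
    missing = set(DISORDER_IDS) - set(societal)
    if missing:
        raise CompletenessError(f"societal costs missing for {sorted(missing)}")

    def group(g: str) -> GroupSummary:
        return _group_summary([s for d, s in societal.items() if group_of(d) == g])

    groups = {
        MENTAL: group(MENTAL),
        NEUROLOGICAL: group(NEUROLOGICAL),
        "all": _group_summary(list(societal.values())),
    }
    grand = groups["all"]

    def shares_of(g: GroupSummary) -> dict[str, float]:
        if g.total == 0:
            return {c: 0.0 for c in CATEGORIES}
        return {
            "healthcare": 100.0 * g.healthcare / g.total,
            "nonmedical": 100.0 * g.nonmedical / g.total,
            "indirect": 100.0 * g.indirect / g.total,
        }

    return RollupSummary(
        groups=groups,
        shares=shares_of(grand),
        group_shares={g: shares_of(s) for g, s in groups.items() if g != "all"},
        cost_per_inhabitant=(grand.total * 1e6 / population) if population else None,
    )


__all__ = [
    "OBSERVED",
    "IMPUTED",
    "FORCED_ZERO",
    "UNAVAILABLE_ZERO",
    "CategoryCost",
    "PerPatientCost",
    "SocietalCost",
    "GroupSummary",
    "RollupSummary",
    "included_observations",
    "category_mean",
    "category_table",
    "impute_missing",
    "combine_subtypes",
    "per_patient_costs",
    "patient_count",
    "societal_cost",
    "societal_costs",
    "disorder_indirect_basis",
    "rollup",
]
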