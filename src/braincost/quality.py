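"""Quality-restricted re-analysis.

The study-quality label is a per-row input (it comes from a 5-item appraisal
questionnaire administered by reviewers; this module does not score
articles).  The sensitivity analysis reruns the whole pooling pipeline on the
high-quality subset and reports per-disorder and overall deltas.

Fallback rule: restriction must not manufacture evidence.  A pooling cell
(disorder or subtype x category) that loses all its observations keeps its
baseline value and is flagged, so fully-imputed disorders and categories with
no high-quality evidence are unaffected by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

from .aggregate import (
    category_table,
    impute_missing,
    patient_count,
    per_patient_costs,
    societal_costs,
    PerPatientCost,
    combine_subtypes,
)
from .corpus import CostObservation, DisorderConfig, ReferenceSet
from .harmonize import HarmonizedObservation
from .vocab import CATEGORIES, DISORDER_IDS


@dataclass(frozen=True)
class QualityItems:
    """Answers to the five appraisal items (None = ambiguous / not assessable):
    perspective specified, design justified, all relevant costs included,
    measured adequately, uncertainty assessed."""

    perspective_specified: bool | None = None
    design_justified: bool | None = None
    costs_complete: bool | None = None
    measured_adequately: bool | None = None
    uncertainty_assessed: bool | None = None

    def label(self, min_positive: int = 5) -> bool:
        """Derive a high-quality label: at least ``min_positive`` unambiguous
        positive answers (default: every unambiguous item positive and none
        negative).  The appraisal cut-off is a user choice, not a fixed rule."""
        answers = [
            self.perspective_specified,
            self.design_justified,
            self.costs_complete,
            self.measured_adequately,
            self.uncertainty_assessed,
        ]
        if any(a is False for a in answers):
            return False
        return sum(a is True for a in answers) >= min(min_positive, 5)


def restrict_corpus(
    corpus: Iterable[CostObservation],
    predicate: Callable[[CostObservation], bool] = lambda o: o.quality_high,
) -> list[CostObservation]:
    """Keep only rows passing ``predicate`` (default: the high-quality flag)."""
    return [o for o in corpus if predicate(o)]


@dataclass(frozen=True)
class DisorderDelta:
    disorder_id: str
    baseline_total: float  # societal, EUR million
    restricted_total: float
    delta_millions: float
    delta_per_patient: float
    fallback: bool  # True when baseline values were (partly) retained


@dataclass(frozen=True)
class SensitivityResult:
    per_disorder: dict[str, DisorderDelta]
    overall_delta_millions: float
    overall_delta_pct: float
    baseline_total: float
    restricted_total: float


def restricted_per_patient_costs(
    harmonized: Iterable[HarmonizedObservation],
    refs: ReferenceSet,
    configs: Mapping[str, DisorderConfig],
    include_incidence: bool = False,
    predicate: Callable[[CostObservation], bool] = lambda o: o.quality_high,
) -> tuple[dict[str, PerPatientCost], set[str]]:
    """Pool the high-quality subset with cell-level fallback to baseline.

    Returns the restricted per-patient costs and the set of disorders where
    at least one cell fell back to its baseline value.
    """
    harmonized = list(harmonized)
    baseline_table = category_table(harmonized, configs, include_incidence)
    restricted_obs = [o for o in harmonized if predicate(o)]
    restricted_table = category_table(restricted_obs, configs, include_incidence)

    flagged: set[str] = set()
    merged: dict[tuple[str, str | None], dict[str, float | None]] = {}
    for cell, means in restricted_table.items():
        merged_cell: dict[str, float | None] = {}
        for cat in CATEGORIES:
            if means[cat] is None and baseline_table[cell][cat] is not None:
                merged_cell[cat] = baseline_table[cell][cat]
                flagged.add(cell[0])
            else:
                merged_cell[cat] = means[cat]
        merged[cell] = merged_cell

    completed = impute_missing(merged, refs, configs)
    out: dict[str, PerPatientCost] = {}
    for d in DISORDER_IDS:
        weights = configs[d].subtype_weights if d in configs else None
        if weights:
            out[d] = combine_subtypes({s: completed[(d, s)] for s in weights}, weights, d)
        else:
            cell = completed[(d, None)]
            out[d] = PerPatientCost(d, cell["healthcare"], cell["nonmedical"], cell["indirect"])
    return out, flagged


def quality_sensitivity(
    harmonized: Iterable[HarmonizedObservation],
    refs: ReferenceSet,
    configs: Mapping[str, DisorderConfig],
    include_incidence: bool = False,
    predicate: Callable[[CostObservation], bool] = lambda o: o.quality_high,
) -> SensitivityResult:
    """Rerun the pipeline on high-quality rows and report deltas.

    All deltas are computed on unrounded values; the overall delta equals the
    sum of per-disorder deltas exactly.
    """
    harmonized = list(harmonized)
    base_ppc = per_patient_costs(harmonized, refs, configs, include_incidence)
    base_soc = societal_costs(base_ppc, refs, harmonized)
    restr_ppc, flagged = restricted_per_patient_costs(
        harmonized, refs, configs, include_incidence, predicate
    )
    restr_soc = societal_costs(restr_ppc, refs, harmonized)

    per_disorder: dict[str, DisorderDelta] = {}
    for d in DISORDER_IDS:
        n = patient_count(refs.prevalence[d], refs.population)
        delta = restr_soc[d].total - base_soc[d].total
        per_disorder[d] = DisorderDelta(
            disorder_id=d,
            baseline_total=base_soc[d].total,
            restricted_total=restr_soc[d].total,
            delta_millions=delta,
            delta_per_patient=restr_ppc[d].total - base_ppc[d].total,
            fallback=d in flagged,
        )
    baseline_total = sum(s.total for s in base_soc.values())
    restricted_total = sum(s.total for s in restr_soc.values())
    overall = restricted_total - baseline_total
    return SensitivityResult(
        per_disorder=per_disorder,
        overall_delta_millions=overall,
        overall_delta_pct=100.0 * overall / baseline_total if baseline_total else 0.0,
        baseline_total=baseline_total,
        restricted_total=restricted_total,
    )


__all__ = [
    "QualityItems",
    "restrict_corpus",
    "restricted_per_patient_costs",
    "quality_sensitivity",
    "DisorderDelta",
    "SensitivityResult",
]
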