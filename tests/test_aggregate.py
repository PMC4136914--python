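"""Pooling, imputation, subtype combination, societal scaling and roll-up."""

from dataclasses import replace

import pytest
from hypothesis import given, settings, strategies as st

from braincost.aggregate import (
    FORCED_ZERO,
    IMPUTED,
    OBSERVED,
    UNAVAILABLE_ZERO,
    CategoryCost,
    PerPatientCost,
    category_mean,
    combine_subtypes,
    included_observations,
    patient_count,
    per_patient_costs,
    rollup,
    societal_cost,
)
from braincost.corpus import CostObservation, PrevalenceEntry
from braincost.errors import CompletenessError, ConfigurationError
from braincost.harmonize import harmonize_corpus
from braincost.vocab import DISORDER_IDS


def _harmonized(refs, rows):
    return harmonize_corpus([CostObservation(**r) for r in rows], refs)


def _flat_configs():
    from braincost.synthetic import default_disorder_configs

    return default_disorder_configs()


class TestCategoryMean:
    def test_epilepsy_healthcare_mean(self, bundle):
        obs = included_observations(bundle.harmonized)
        assert category_mean(obs, "epilepsy", "healthcare") == pytest.approx(4734, rel=0.01)

    def test_absence_is_skipped_not_zero_filled(self, bundle):
        # only one epilepsy article reports indirect costs; the pooled value
        # is that article's harmonized amount, not half of it
        obs = included_observations(bundle.harmonized)
        assert category_mean(obs, "epilepsy", "indirect") == pytest.approx(1827, rel=0.01)

    def test_mean_of_single_observation(self, evidence):
        _, refs, _ = evidence
        obs = _harmonized(
            refs,
            [dict(study_id="a", disorder_id="stroke", costing_year=2010, currency="EUR", cost_healthcare=5000.0)],
        )
        assert category_mean(obs, "stroke", "healthcare") == 5000.0
        assert category_mean(obs, "stroke", "indirect") is None

    def test_explicit_zero_participates(self, evidence):
        _, refs, _ = evidence
        obs = _harmonized(
            refs,
            [
                dict(study_id="a", disorder_id="stroke", costing_year=2010, currency="EUR", cost_indirect=0.0),
                dict(study_id="b", disorder_id="stroke", costing_year=2010, currency="EUR", cost_indirect=100.0),
            ],
        )
        assert category_mean(obs, "stroke", "indirect") == 50.0


class TestImputationHierarchy:
    def test_observed_then_median_then_zero(self, bundle):
        ppc = bundle.per_patient["psychotic_disorders"]
        assert ppc.healthcare.provenance == OBSERVED
        assert ppc.indirect.provenance == IMPUTED
        assert ppc.nonmedical == CategoryCost(0.0, UNAVAILABLE_ZERO)

    def test_disorder_without_evidence_is_fully_imputed(self, bundle):
        ppc = bundle.per_patient["eating_disorders"]
        assert {c.provenance for c in (ppc.healthcare, ppc.nonmedical, ppc.indirect)} == {IMPUTED}
        assert ppc.total == pytest.approx(364 + 45 + 90)

    def test_dementia_indirect_forced_zero_despite_evidence(self, bundle):
        # two articles report dementia indirect costs, but patients are
        # assumed outside the working population
        assert bundle.per_patient["dementia"].indirect == CategoryCost(0.0, FORCED_ZERO)

    def test_imputation_off_only_decreases_totals(self, evidence, bundle):
        from braincost.pipeline import estimate

        corpus, refs, configs = evidence
        stripped = estimate(corpus, refs, configs, imputation=False)
        for d in DISORDER_IDS:
            assert stripped.per_patient[d].total <= bundle.per_patient[d].total + 1e-9


class TestCombineSubtypes:
    def _cc(self, v):
        return {c: CategoryCost(v, OBSERVED) for c in ("healthcare", "nonmedical", "indirect")}

    def test_single_subtype_identity(self):
        out = combine_subtypes({"a": self._cc(100.0)}, {"a": 1.0}, "stroke")
        assert out.healthcare.amount == 100.0

    def test_equal_weights_average(self):
        out = combine_subtypes(
            {"a": self._cc(100.0), "b": self._cc(300.0)}, {"a": 0.5, "b": 0.5}, "stroke"
        )
        assert out.total == pytest.approx(3 * 200.0)

    def test_weight_mismatch_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="do not match"):
            combine_subtypes({"a": self._cc(1.0)}, {"a": 0.5, "b": 0.5}, "stroke")

    def test_headache_composite_is_between_subtype_extremes(self, bundle):
        ppc = bundle.per_patient["headache"]
        # subtype healthcare means range from ~19 (tension-type) to ~534
        # (migraine); the prevalence-weighted composite must lie within
        assert 19 <= ppc.healthcare.amount <= 534
        assert ppc.total == pytest.approx(401, rel=0.01)


class TestPatientCount:
    def test_direct_count_passes_through(self):
        e = PrevalenceEntry("dementia", n_patients=608_711)
        assert patient_count(e, 46_000_000) == 608_711

    def test_proportion_times_population(self):
        e = PrevalenceEntry("stroke", proportion=0.01)
        assert patient_count(e, 1_000_000) == 10_000

    def test_zero_proportion(self):
        e = PrevalenceEntry("stroke", proportion=0.0)
        assert patient_count(e, 1_000_000) == 0


class TestSocietalCost:
    def _ppc(self, h, m, i):
        return PerPatientCost(
            "stroke",
            CategoryCost(h, OBSERVED),
            CategoryCost(m, OBSERVED),
            CategoryCost(i, OBSERVED),
        )

    def test_millions_scaling(self):
        soc = societal_cost(self._ppc(1000.0, 500.0, 250.0), 2_000_000)
        assert soc.healthcare == pytest.approx(2000.0)
        assert soc.total == pytest.approx(3500.0)

    def test_zero_patients_zero_cost(self):
        soc = societal_cost(self._ppc(1000.0, 500.0, 250.0), 0)
        assert soc.total == 0.0

    def test_working_age_fraction_only_scales_indirect(self):
        soc = societal_cost(self._ppc(100.0, 100.0, 100.0), 1_000_000, working_age_fraction=0.5)
        assert soc.healthcare == pytest.approx(100.0)
        assert soc.indirect == pytest.approx(50.0)

    def test_all_ages_basis_ignores_fraction(self):
        soc = societal_cost(
            self._ppc(0.0, 0.0, 100.0), 1_000_000, 0.5, indirect_basis="all_ages"
        )
        assert soc.indirect == pytest.approx(100.0)

    def test_dementia_societal_total(self, bundle):
        # ~25,300 EUR/patient x 608,711 patients ~ 15.4 EUR billion
        soc = bundle.societal["dementia"]
        assert soc.total == pytest.approx(soc.n_patients * bundle.per_patient["dementia"].total / 1e6)

    def test_eating_disorders_magnitude(self, bundle):
        assert bundle.societal["eating_disorders"].total == pytest.approx(65, abs=1)


class TestRollup:
    def test_additivity_and_share_normalization(self, bundle):
        g = bundle.summary.groups
        assert g["mental"].total + g["neurological"].total == pytest.approx(g["all"].total)
        assert sum(bundle.summary.shares.values()) == pytest.approx(100.0)
        by_disorder = sum(s.total for s in bundle.societal.values())
        assert by_disorder == pytest.approx(g["all"].total)

    def test_cost_per_inhabitant_is_total_over_population(self, bundle):
        per_inhabitant = bundle.summary.cost_per_inhabitant
        assert per_inhabitant == pytest.approx(bundle.grand_total * 1e6 / 46_000_000)

    def test_missing_disorder_is_completeness_error(self, bundle):
        partial = {d: s for d, s in bundle.societal.items() if d != "stroke"}
        with pytest.raises(CompletenessError, match="stroke"):
            rollup(partial)

    def test_single_disorder_degenerate_rollup(self, bundle):
        from braincost.aggregate import SocietalCost

        zeroed = {
            d: (s if d == "dementia" else SocietalCost(d, s.n_patients, 0.0, 0.0, 0.0))
            for d, s in bundle.societal.items()
        }
        summary = rollup(zeroed)
        assert summary.groups["all"].total == pytest.approx(bundle.societal["dementia"].total)
        assert summary.groups["neurological"].total == pytest.approx(
            bundle.societal["dementia"].total
        )


class TestBruteForceOracle:
    def test_tiny_corpus_equals_hand_computation(self, evidence):
        """<=5 observations: pipeline equals independent mean/multiply/sum."""
        _, refs, _ = evidence
        configs = _flat_configs()
        rows = [
            dict(study_id="a", disorder_id="epilepsy", costing_year=2010, currency="EUR",
                 cost_healthcare=4000.0, cost_nonmedical=600.0),
            dict(study_id="b", disorder_id="epilepsy", costing_year=2010, currency="EUR",
                 cost_healthcare=5000.0, cost_indirect=1800.0),
            dict(study_id="c", disorder_id="stroke", costing_year=2010, currency="EUR",
                 cost_healthcare=3000.0),
        ]
        obs = _harmonized(refs, rows)
        ppc = per_patient_costs(obs, refs, configs)
        # hand computation (independent of the implementation path):
        assert ppc["epilepsy"].healthcare.amount == pytest.approx((4000 + 5000) / 2)
        assert ppc["epilepsy"].nonmedical.amount == pytest.approx(600.0)
        assert ppc["epilepsy"].indirect.amount == pytest.approx(1800.0)
        assert ppc["epilepsy"].total == pytest.approx(4500 + 600 + 1800)
        assert ppc["stroke"].healthcare.amount == pytest.approx(3000.0)
        n = refs.prevalence["epilepsy"].n_patients
        soc = societal_cost(ppc["epilepsy"], n)
        assert soc.total == pytest.approx((4500 + 600 + 1800) * n / 1e6)

    @settings(max_examples=25, deadline=None)
    @given(bump=st.floats(0.0, 1e5))
    def test_monotonicity_in_observation_amounts(self, evidence, bundle, bump):
        """Raising one article's amount weakly raises the affected totals."""
        corpus, refs, configs = evidence
        from braincost.pipeline import estimate

        bumped = [
            replace(o, cost_healthcare=o.cost_healthcare + bump)
            if o.study_id == "sancho2008"
            else o
            for o in corpus
        ]
        out = estimate(bumped, refs, configs)
        assert out.per_patient["epilepsy"].total >= bundle.per_patient["epilepsy"].total - 1e-9
        assert out.grand_total >= bundle.grand_total - 1e-9
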