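"""Triangular fitting, sampling, summaries and pooled statistics."""

import numpy as np
import pytest
from scipy import stats

from braincost.errors import ConfigurationError
from braincost.montecarlo import (
    DEFAULT_ELIGIBLE,
    TriangularDist,
    fit_triangular,
    pooled_median_stats,
    sample_disorder,
    simulate,
    simulated_vs_observed,
    summarize,
)


class TestFitTriangular:
    def test_mode_is_the_mean(self):
        d = fit_triangular([2.0, 3.0, 7.0])
        assert (d.lower, d.mode, d.upper) == (2.0, 4.0, 7.0)

    def test_single_value_is_degenerate(self):
        d = fit_triangular([5000.0])
        assert d.degenerate and d.mode == 5000.0

    def test_two_values_symmetric(self):
        d = fit_triangular([10.0, 30.0])
        assert d.mode == 20.0
        assert d.analytic_mean == pytest.approx(20.0)

    def test_median_mode_variant(self):
        d = fit_triangular([1.0, 2.0, 9.0], mode="median")
        assert d.mode == 2.0

    def test_empty_input_is_an_error(self):
        with pytest.raises(ConfigurationError):
            fit_triangular([])

    def test_unordered_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            TriangularDist(5.0, 1.0, 10.0)


class TestSampleDisorder:
    def test_degenerate_components_sum_exactly(self):
        dists = {
            "healthcare": TriangularDist(10, 10, 10),
            "nonmedical": TriangularDist(20, 20, 20),
            "indirect": TriangularDist(30, 30, 30),
        }
        samples = sample_disorder(dists, 100, rng=0)
        assert np.all(samples == 60.0)

    def test_seeded_reproducibility(self):
        dists = {"healthcare": TriangularDist(0.0, 5.0, 10.0)}
        a = sample_disorder(dists, 500, rng=42)
        b = sample_disorder(dists, 500, rng=42)
        assert np.array_equal(a, b)

    def test_sampler_matches_closed_form_within_3_se(self):
        """10^5 draws from Triangular(0, 5, 10): mean and the 5%/95%
        quantiles agree with the analytic distribution within 3 standard
        errors (independent oracle: scipy.stats.triang)."""
        n = 100_000
        tri = stats.triang(c=0.5, loc=0.0, scale=10.0)
        samples = sample_disorder({"healthcare": TriangularDist(0.0, 5.0, 10.0)}, n, rng=2024)
        se_mean = tri.std() / np.sqrt(n)
        assert samples.mean() == pytest.approx(tri.mean(), abs=3 * se_mean)
        for p in (0.05, 0.95):
            q_true = tri.ppf(p)
            se_q = np.sqrt(p * (1 - p) / n) / tri.pdf(q_true)
            assert np.quantile(samples, p) == pytest.approx(q_true, abs=3 * se_q)

    def test_support_containment(self):
        dists = {
            "healthcare": TriangularDist(1.0, 2.0, 4.0),
            "indirect": TriangularDist(10.0, 11.0, 12.0),
        }
        samples = sample_disorder(dists, 10_000, rng=7)
        assert samples.min() >= 11.0 and samples.max() <= 16.0


class TestSummarize:
    def test_constant_samples(self):
        assert summarize(np.full(100, 60.0)) == (60.0, 60.0, 60.0)

    def test_order_statistics_with_linear_interpolation(self):
        mean, lo, hi = summarize(np.arange(1, 1001, dtype=float), level=0.90)
        assert lo == pytest.approx(50.95)
        assert hi == pytest.approx(950.05)

    def test_bad_level_rejected(self):
        with pytest.raises(ConfigurationError):
            summarize(np.ones(5), level=1.5)


class TestPooledMedian:
    def test_two_constant_disorders(self):
        stats_ = pooled_median_stats(
            {"a": np.full(50, 100.0), "b": np.full(50, 300.0)}, threshold=150.0
        )
        assert np.all(stats_.median_samples == 200.0)
        assert stats_.exceedance_probability == 1.0

    def test_seven_degenerate_disorders_pin_the_4th_order_statistic(self):
        samples = {f"d{i}": np.full(20, float(i)) for i in range(1, 8)}
        stats_ = pooled_median_stats(samples, threshold=3.5)
        assert np.all(stats_.median_samples == 4.0)
        assert stats_.interval == (4.0, 4.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigurationError, match="n_iter"):
            pooled_median_stats({"a": np.ones(10), "b": np.ones(11)}, 1.0)


class TestSimulatedVsObserved:
    def _baseline(self, total):
        from braincost.aggregate import CategoryCost, OBSERVED, PerPatientCost

        cc = CategoryCost(total / 3, OBSERVED)
        return {"stroke": PerPatientCost("stroke", cc, cc, cc)}

    def test_symmetric_inputs_give_zero_difference(self):
        assert simulated_vs_observed({"stroke": 300.0}, self._baseline(300.0)) == 0.0

    def test_right_skew_gives_positive_difference(self):
        # Triangular(0, 100, 400): analytic mean (0+100+400)/3 > mode 100
        d = TriangularDist(0.0, 100.0, 400.0)
        assert d.analytic_mean > d.mode
        assert simulated_vs_observed({"stroke": d.analytic_mean * 3}, self._baseline(300.0)) > 0


class TestFullSimulation:
    def test_eligible_set_and_reproducibility(self, evidence, bundle):
        _, refs, configs = evidence
        kw = dict(n_iter=200, seed=11)
        sim1 = simulate(bundle.harmonized, refs, configs, bundle.per_patient, **kw)
        sim2 = simulate(bundle.harmonized, refs, configs, bundle.per_patient, **kw)
        assert set(sim1.per_disorder) == set(DEFAULT_ELIGIBLE)
        for d in sim1.per_disorder:
            assert np.array_equal(sim1.per_disorder[d].samples, sim2.per_disorder[d].samples)

    def test_single_article_cells_have_zero_width(self, evidence, bundle):
        """Parkinson's: healthcare and indirect come from one article each,
        so only the two-article non-medical cell spreads the total."""
        _, refs, configs = evidence
        sim = simulate(bundle.harmonized, refs, configs, bundle.per_patient, n_iter=500, seed=5)
        pd_sim = sim.per_disorder["parkinsons_disease"]
        nm_values = sorted(
            o.cost_nonmedical
            for o in bundle.harmonized
            if o.disorder_id == "parkinsons_disease" and o.cost_nonmedical is not None
        )
        width = nm_values[-1] - nm_values[0]
        assert pd_sim.samples.max() - pd_sim.samples.min() <= width

    def test_samples_lie_in_model_support(self, evidence, bundle):
        _, refs, configs = evidence
        from braincost.montecarlo import build_disorder_model

        sim = simulate(bundle.harmonized, refs, configs, bundle.per_patient, n_iter=500, seed=5)
        for d, summary in sim.per_disorder.items():
            model = build_disorder_model(
                bundle.harmonized, d, refs, configs, bundle.per_patient
            )
            lo, hi = model.support
            assert summary.samples.min() >= lo - 1e-9
            assert summary.samples.max() <= hi + 1e-9
            assert lo - 1e-9 <= summary.mean <= hi + 1e-9
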