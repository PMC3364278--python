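"""Gaussian mixture density, EM, greedy growth, sampling and reporting."""

import json

import numpy as np
import pytest
from scipy import integrate

from hrvmix import (
    GaussianComponent,
    GaussianMixture,
    dominant_components,
    em_refit,
    fit_greedy,
    insert_best_component,
    log_likelihood,
    mixture_pdf,
    responsibilities,
    sample_mixture,
)
from hrvmix.mixture import mixture_logpdf


def mix(*triples):
    return GaussianMixture.from_arrays(
        [t[0] for t in triples], [t[1] for t in triples], [t[2] for t in triples]
    )


class TestDensity:
    def test_standard_normal_mode(self):
        m = mix((1.0, 0.0, 1.0))
        assert mixture_pdf(m, [0.0])[0] == pytest.approx(1.0 / np.sqrt(2 * np.pi), rel=1e-12)

    def test_symmetry_of_balanced_pair(self):
        m = mix((0.5, -3.0, 2.0), (0.5, 3.0, 2.0))
        x = np.linspace(0.0, 8.0, 50)
        np.testing.assert_allclose(mixture_pdf(m, x), mixture_pdf(m, -x), rtol=1e-12)

    def test_density_integrates_to_one(self):
        m = mix((0.45, 60.0, 16.0), (0.35, 85.0, 30.0), (0.2, 110.0, 9.0))
        sd = np.sqrt(m.variance)
        total, _ = integrate.quad(lambda x: mixture_pdf(m, [x])[0],
                                  m.mean - 10 * sd, m.mean + 10 * sd, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GaussianMixture(
                components=(
                    GaussianComponent(0.5, 60.0, 4.0),
                    GaussianComponent(0.4, 80.0, 4.0),
                )
            )


class TestLogLikelihood:
    def test_single_point_closed_form(self):
        m = mix((1.0, 5.0, 1.0))
        assert log_likelihood(m, [5.0]) == pytest.approx(-0.5 * np.log(2 * np.pi), rel=1e-12)

    def test_additivity_under_duplication(self, rng):
        m = mix((0.6, 70.0, 25.0), (0.4, 95.0, 16.0))
        data = rng.normal(75, 8, 40)
        assert log_likelihood(m, np.tile(data, 2)) == pytest.approx(
            2 * log_likelihood(m, data), rel=1e-12
        )

    def test_matches_naive_double_sum(self, rng):
        """Log-sum-exp path equals the direct sum-of-exponentials evaluation."""
        m = mix((0.5, 60.0, 16.0), (0.3, 90.0, 25.0), (0.2, 120.0, 36.0))
        data = rng.normal(80, 20, 50)
        naive = 0.0
        for x in data:
            p = sum(
                c.weight * np.exp(-0.5 * (x - c.mean) ** 2 / c.variance)
                / np.sqrt(2 * np.pi * c.variance)
                for c in m.components
            )
            naive += np.log(p)
        assert log_likelihood(m, data) == pytest.approx(naive, abs=1e-10)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            log_likelihood(mix((1.0, 0.0, 1.0)), [])

    def test_responsibilities_rows_sum_to_one(self, rng):
        m = mix((0.7, 60.0, 9.0), (0.3, 100.0, 25.0))
        g = responsibilities(m, rng.normal(80, 15, 200))
        np.testing.assert_allclose(g.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((g >= 0) & (g <= 1))


class TestEM:
    def test_k1_converges_to_sample_moments(self, rng):
        data = rng.normal(75, 6, 500)
        start = mix((1.0, 0.0, 1.0e4))
        fitted, _ = em_refit(start, data)
        c = fitted.components[0]
        assert c.mean == pytest.approx(data.mean(), abs=1e-9)
        assert c.variance == pytest.approx(data.var(), rel=1e-9)  # biased MLE variance

    def test_degenerate_point_mass_hits_variance_floor(self):
        data = np.full(50, 66.0)
        fitted, _ = em_refit(mix((1.0, 60.0, 25.0)), data)
        c = fitted.components[0]
        assert c.mean == pytest.approx(66.0)
        assert c.variance > 0  # floored, not collapsed

    def test_monotone_loglikelihood_on_random_datasets(self, rng):
        """EM never decreases the log-likelihood (checked across datasets and
        deliberately poor random starts)."""
        for _ in range(20):
            data = np.concatenate(
                [rng.normal(rng.uniform(50, 70), rng.uniform(2, 6), 150),
                 rng.normal(rng.uniform(80, 110), rng.uniform(2, 8), 100)]
            )
            start = mix(
                (0.5, rng.uniform(40, 120), rng.uniform(1, 100)),
                (0.5, rng.uniform(40, 120), rng.uniform(1, 100)),
            )
            before = log_likelihood(start, data)
            fitted, _ = em_refit(start, data)
            assert log_likelihood(fitted, data) >= before - 1e-9


class TestGreedyGrowth:
    def test_insertion_targets_unoccupied_mode(self, rng):
        """Oracle: exhaustive grid search over (mu, var, alpha) agrees that the
        best second component sits in the empty mode."""
        data = np.concatenate([rng.normal(60, 2, 600), rng.normal(100, 2, 400)])
        start = mix((1.0, 60.0, 4.0))
        grown = insert_best_component(start, data, rng=np.random.default_rng(0))
        assert grown is not None
        new = grown.components[-1]
        assert abs(new.mean - 100) < abs(new.mean - 60)

        # brute-force oracle over a coarse parameter grid
        best_ll, best_mu = -np.inf, None
        base_lp = mixture_logpdf(start, data)
        for mu in np.linspace(40, 120, 33):
            for var in (1.0, 4.0, 16.0):
                for alpha in (0.2, 0.4, 0.6):
                    cand_lp = -0.5 * (np.log(2 * np.pi * var) + (data - mu) ** 2 / var)
                    ll = np.logaddexp(np.log1p(-alpha) + base_lp,
                                      np.log(alpha) + cand_lp).sum()
                    if ll > best_ll:
                        best_ll, best_mu = ll, mu
        assert abs(best_mu - 100) < abs(best_mu - 60)
        assert log_likelihood(grown, data) >= best_ll - 1.0  # refined beats coarse grid

    def test_accepted_insertion_improves_loglik(self, rng):
        data = np.concatenate([rng.normal(55, 3, 400), rng.normal(95, 5, 400)])
        start = mix((1.0, float(data.mean()), float(data.var())))
        before = log_likelihood(start, data)
        grown = insert_best_component(start, data, rng=np.random.default_rng(1))
        assert grown is not None
        assert log_likelihood(grown, data) > before

    def test_trace_loglik_nondecreasing(self, three_component_sample):
        values, _ = three_component_sample
        _, trace = fit_greedy(values[:4000], seed=0)
        ll = trace.log_likelihoods
        assert np.all(np.diff(ll) >= -1e-9)

    def test_single_gaussian_recovery(self):
        rng = np.random.default_rng(42)
        data = rng.normal(70, 5, 5000)
        m, _ = fit_greedy(data, seed=42)
        _, nd = dominant_components(m)
        assert nd == 1
        c = m.components[0]
        assert abs(c.mean - 70) < 0.5
        assert abs(c.variance - 25) < 3

    def test_three_component_recovery(self, three_component_truth, three_component_sample):
        values, _ = three_component_sample
        m, _ = fit_greedy(values, seed=11)
        sub, nd = dominant_components(m)
        assert nd == 3
        np.testing.assert_allclose(sub.means, three_component_truth.means, atol=1.0)
        np.testing.assert_allclose(sub.weights, three_component_truth.weights, atol=0.03)
        np.testing.assert_allclose(sub.variances, three_component_truth.variances, rtol=0.15)

    def test_weight_sorted_output(self, three_component_sample):
        values, _ = three_component_sample
        m, _ = fit_greedy(values[:3000], seed=3)
        w = m.weights
        assert np.all(np.diff(w) <= 1e-12)


class TestSampling:
    def test_degenerate_single_component(self):
        values, z = sample_mixture(mix((1.0, 70.0, 4.0)), 500, seed=0)
        assert np.all(z == 0)
        assert values.std() == pytest.approx(2.0, rel=0.2)

    def test_assignment_frequencies_match_weights(self, three_component_truth):
        n = 10_000
        _, z = sample_mixture(three_component_truth, n, seed=5)
        freqs = np.bincount(z, minlength=3) / n
        w = three_component_truth.weights
        se = np.sqrt(w * (1 - w) / n)
        np.testing.assert_array_less(np.abs(freqs - w), 3 * se)

    def test_sample_mean_matches_mixture_mean(self, three_component_truth):
        n = 10_000
        values, _ = sample_mixture(three_component_truth, n, seed=6)
        se = np.sqrt(three_component_truth.variance / n)
        assert abs(values.mean() - three_component_truth.mean) < 3 * se

    def test_negative_mass_warning(self):
        with pytest.warns(RuntimeWarning, match="non-positive"):
            sample_mixture(mix((1.0, 0.5, 1.0)), 2000, seed=0)

    def test_reproducible_under_seed(self, three_component_truth):
        a, _ = sample_mixture(three_component_truth, 100, seed=9)
        b, _ = sample_mixture(three_component_truth, 100, seed=9)
        np.testing.assert_array_equal(a, b)


class TestDominantAndSerialization:
    def test_threshold_counting(self):
        m = mix((0.5, 60, 4), (0.3, 75, 4), (0.19, 90, 4), (0.01, 120, 4))
        _, nd = dominant_components(m, threshold=0.05)
        assert nd == 3
        _, all_nd = dominant_components(m, threshold=0.0)
        assert all_nd == 4

    def test_no_component_passes(self):
        m = mix(*[(0.1, 50 + 5 * i, 4) for i in range(10)])
        sub, nd = dominant_components(m, threshold=0.5)
        assert sub is None and nd == 0

    def test_renormalized_weights_sum_to_one(self):
        m = mix((0.6, 60, 4), (0.3, 80, 4), (0.1, 100, 4))
        sub, _ = dominant_components(m, threshold=0.2)
        assert sub.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_json_round_trip(self, tmp_path):
        m = mix((0.55, 61.25, 17.5), (0.45, 88.0, 30.25))
        f = tmp_path / "mixture.json"
        m.to_json(f, meta={"n": 100, "loglik": -1.5, "seed": 3, "stopping": "bic_converged"})
        doc = json.loads(f.read_text())
        assert doc["meta"]["stopping"] == "bic_converged"
        back = GaussianMixture.from_json(f)
        np.testing.assert_array_equal(back.weights, m.weights)
        np.testing.assert_array_equal(back.means, m.means)
        np.testing.assert_array_equal(back.variances, m.variances)

    def test_sort_tie_break_by_mean(self):
        m = mix((0.5, 90.0, 4.0), (0.5, 60.0, 4.0)).sorted_by_weight()
        assert m.means[0] == 60.0  # equal weights -> ascending mean
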