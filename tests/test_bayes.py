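"""Classifier behaviour: likelihood tables, posteriors, Bayes combination,
missing-feature handling and the evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prmpred import (
    BinnedNaiveBayes,
    class_posterior,
    combine_posteriors,
    evaluate,
    fit_naive_bayes,
)
from prmpred.bayes import aggregate_pairs, PredictionRecord
from prmpred.errors import DegenerateTraining, NoEvidence, UndefinedMetric


def _simple_data(rng, n=500, informative=True):
    y = np.repeat([1, 0], n)
    if informative:
        x1 = np.concatenate([rng.beta(6, 2, n), rng.beta(2, 6, n)])
    else:
        x1 = rng.uniform(size=2 * n)
    x2 = rng.uniform(size=2 * n)
    return np.column_stack([x1, x2]), y


class TestFit:
    def test_tables_normalized_and_positive(self):
        rng = np.random.default_rng(0)
        X, y = _simple_data(rng)
        m = BinnedNaiveBayes(feature_bounds=[(0, 1), (0, 1)]).fit(X, y)
        sums = m.likelihoods_.sum(axis=2)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert np.all(m.likelihoods_ > 0)
        assert 0 < m.prior_ < 1

    def test_uninformative_feature_has_unit_likelihood_ratio(self):
        rng = np.random.default_rng(1)
        X, y = _simple_data(rng, n=20000, informative=False)
        m = BinnedNaiveBayes(feature_bounds=[(0, 1), (0, 1)]).fit(X, y)
        ratio = m.likelihoods_[1, 0] / m.likelihoods_[0, 0]
        assert np.allclose(ratio, 1.0, atol=0.12)

    def test_separating_feature_saturates_as_smoothing_vanishes(self):
        # positives all in the top bin, negatives never
        X = np.concatenate([np.full(50, 0.95), np.full(50, 0.05)])[:, None]
        y = np.repeat([1, 0], 50)
        m = BinnedNaiveBayes(smoothing=1e-9, feature_bounds=[(0, 1)]).fit(X, y)
        post = class_posterior(m, [0.95])
        assert post == pytest.approx(1.0, abs=1e-6)

    def test_recovers_binned_histograms(self):
        rng = np.random.default_rng(2)
        n = 5000
        pos = rng.beta(5, 2, n)
        neg = rng.beta(2, 5, n)
        X = np.concatenate([pos, neg])[:, None]
        y = np.repeat([1, 0], n)
        m = BinnedNaiveBayes(n_bins=10, smoothing=0.0,
                             feature_bounds=[(0, 1)]).fit(X, y)
        hist_pos = np.histogram(pos, bins=np.linspace(0, 1, 11))[0] / n
        assert np.allclose(m.likelihoods_[1, 0], hist_pos, atol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateTraining):
            BinnedNaiveBayes().fit(np.zeros((5, 2)), np.ones(5))

    def test_sklearn_protocol(self):
        from sklearn.base import clone

        m = BinnedNaiveBayes(n_bins=7, smoothing=0.5)
        m2 = clone(m)
        assert m2.get_params()["n_bins"] == 7


class TestPosterior:
    def test_all_missing_but_one_uninformative_returns_prior(self):
        rng = np.random.default_rng(3)
        X, y = _simple_data(rng, n=5000, informative=False)
        m = BinnedNaiveBayes(prior=0.3, feature_bounds=[(0, 1), (0, 1)]).fit(X, y)
        post = class_posterior(m, [np.nan, 0.5])
        assert post == pytest.approx(0.3, abs=0.05)

    def test_likelihood_ratio_four_gives_point_eight(self):
        m = BinnedNaiveBayes(n_bins=2, prior=0.5, feature_bounds=[(0, 1)])
        m.fit(np.array([[0.9], [0.1]] * 10), np.array([1, 0] * 10))
        # overwrite the table with an exact ratio-4 bin
        m.likelihoods_ = np.array([[[0.8, 0.2]], [[0.2, 0.8]]])
        assert class_posterior(m, [0.9]) == pytest.approx(0.8, abs=1e-12)

    def test_matches_direct_product_of_likelihoods(self):
        rng = np.random.default_rng(4)
        X, y = _simple_data(rng)
        m = BinnedNaiveBayes(feature_bounds=[(0, 1), (0, 1)]).fit(X, y)
        for _ in range(20):
            v = rng.uniform(size=2)
            bins = [
                min(int(np.searchsorted(m.bin_edges_[f], v[f], side="right")),
                    m.n_bins - 1)
                for f in range(2)
            ]
            num = m.prior_ * np.prod([m.likelihoods_[1, f, bins[f]] for f in range(2)])
            den = num + (1 - m.prior_) * np.prod(
                [m.likelihoods_[0, f, bins[f]] for f in range(2)]
            )
            assert class_posterior(m, v) == pytest.approx(num / den, abs=1e-12)

    def test_no_evidence_raises(self):
        rng = np.random.default_rng(5)
        X, y = _simple_data(rng)
        m = BinnedNaiveBayes(feature_bounds=[(0, 1), (0, 1)]).fit(X, y)
        with pytest.raises(NoEvidence):
            class_posterior(m, [np.nan, np.nan])

    def test_missing_feature_equals_model_trained_without_it(self):
        rng = np.random.default_rng(6)
        X, y = _simple_data(rng)
        full = BinnedNaiveBayes(feature_bounds=[(0, 1), (0, 1)]).fit(X, y)
        reduced = BinnedNaiveBayes(feature_bounds=[(0, 1)]).fit(X[:, :1], y)
        for v in (0.1, 0.5, 0.9):
            assert class_posterior(full, [v, np.nan]) == pytest.approx(
                class_posterior(reduced, [v]), abs=1e-12
            )


class TestCombinePosteriors:
    def test_neutral_second_classifier(self):
        for p in (0.1, 0.4, 0.9):
            assert combine_posteriors(p, 0.5, 0.5) == pytest.approx(p, abs=1e-12)

    def test_prior_fixed_point(self):
        for prior in (0.2, 0.5, 0.8):
            assert combine_posteriors(prior, prior, prior) == pytest.approx(
                prior, abs=1e-12
            )

    def test_direct_evaluation(self):
        assert combine_posteriors(0.9, 0.9, 0.5) == pytest.approx(
            0.81 / (0.81 + 0.01), abs=1e-12
        )

    @settings(max_examples=200, derandomize=True)
    @given(
        p1=st.floats(0.01, 0.99),
        p2=st.floats(0.01, 0.99),
        prior=st.floats(0.05, 0.95),
    )
    def test_symmetry_and_bounds(self, p1, p2, prior):
        c = combine_posteriors(p1, p2, prior)
        assert 0.0 <= c <= 1.0
        assert c == pytest.approx(combine_posteriors(p2, p1, prior), abs=1e-12)

    def test_monotone_in_each_argument(self):
        grid = np.linspace(0.05, 0.95, 10)
        for other in (0.2, 0.5, 0.8):
            vals = [combine_posteriors(p, other, 0.5) for p in grid]
            assert all(a < b for a, b in zip(vals, vals[1:]))
            vals = [combine_posteriors(other, p, 0.5) for p in grid]
            assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_boundary_clipping(self):
        assert 0.0 <= combine_posteriors(1.0, 0.5, 0.5) <= 1.0
        assert 0.0 <= combine_posteriors(0.0, 0.0, 0.5) <= 1.0


class TestCalibration:
    def test_posterior_reliability_on_model_generated_data(self):
        # features generated from the fitted model's own class-conditional
        # bins: predicted probabilities should match empirical positive
        # rates per decile
        rng = np.random.default_rng(7)
        n = 20000
        pos = rng.beta(4, 2, n // 2)
        neg = rng.beta(2, 4, n // 2)
        X = np.concatenate([pos, neg])[:, None]
        y = np.repeat([1, 0], n // 2)
        m = BinnedNaiveBayes(feature_bounds=[(0, 1)]).fit(X, y)
        p = m.predict_proba(X)[:, 1]
        for lo in np.arange(0.1, 0.9, 0.2):
            sel = (p >= lo) & (p < lo + 0.2)
            if sel.sum() > 200:
                assert y[sel].mean() == pytest.approx(p[sel].mean(), abs=0.08)


class TestEvaluate:
    def test_perfect_ranking(self):
        y = [0, 0, 1, 1]
        s = [0.1, 0.2, 0.8, 0.9]
        rep = evaluate(y, s, threshold=0.5)
        assert rep.auroc == 1.0
        assert rep.f1 == rep.mcc == rep.acc == 1.0

    def test_random_scores_near_half_auroc(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 4000)
        s = rng.uniform(size=4000)
        rep = evaluate(y, s, threshold=0.5)
        assert rep.auroc == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetric):
            evaluate([1, 1, 1], [0.1, 0.5, 0.9])

    def test_brier_is_mean_squared_error(self):
        y = [0, 1, 1, 0]
        s = [0.2, 0.7, 0.9, 0.4]
        rep = evaluate(y, s, threshold=0.5)
        expected = np.mean([(0.2 - 0) ** 2, (0.7 - 1) ** 2,
                            (0.9 - 1) ** 2, (0.4 - 0) ** 2])
        assert rep.brier == pytest.approx(expected, abs=1e-12)


class TestAggregation:
    def _rec(self, cand, combined):
        return PredictionRecord(candidate_id=cand, p_pep=None, p_pro=None,
                                combined=combined, features={}, decision=False)

    def test_max_over_sites(self):
        recs = [self._rec("a|b|s1", 0.7), self._rec("a|b|s2", 0.95)]
        assert aggregate_pairs(recs) == {"a|b": 0.95}

    def test_noisy_or(self):
        recs = [self._rec("a|b|s1", 0.5), self._rec("a|b|s2", 0.5)]
        assert aggregate_pairs(recs, "noisy-or") == {"a|b": pytest.approx(0.75)}
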