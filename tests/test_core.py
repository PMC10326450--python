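import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatialinfo import (
    ClassifierParams,
    SpatialDataset,
    SpatialInformationModel,
    adjust_pvalues,
    binomial_test,
    classify_pair,
    js_objective,
    normalize_scores,
)
from spatialinfo.core import LOG_QUARTER, inv_softplus, softplus


def _unit_params(alpha=1.0):
    return ClassifierParams(inv_softplus(1.0), inv_softplus(1.0), 0.0, 0.0, np.log(alpha))


class TestClassifier:
    def test_similar_pair_positive(self):
        assert classify_pair(_unit_params(), 1.0, 1.0, 0.0) == pytest.approx(2.0)

    def test_dissimilar_pair_negative(self):
        assert classify_pair(_unit_params(), 1.0, -1.0, 0.0) == pytest.approx(-2.0)

    def test_distance_decay_e_inverse(self):
        # at d = alpha, the logit shrinks by a factor e
        assert classify_pair(_unit_params(alpha=1.0), 1.0, 1.0, 1.0) == pytest.approx(
            2.0 * np.exp(-1), abs=1e-6
        )

    def test_positivity_constraints(self):
        th = ClassifierParams(-50.0, -50.0, 0.0, 0.0, 0.0)
        assert th.ws > 0 and th.wd > 0
        assert th.alpha > 0


class TestJsObjective:
    def test_zero_logits_baseline(self):
        assert js_objective(np.zeros(5), np.zeros(5)) == pytest.approx(
            -2 * np.log(2), abs=1e-12
        )

    def test_perfect_classification_limit(self):
        assert js_objective(np.full(3, 100.0), np.full(3, -100.0)) == pytest.approx(0.0, abs=1e-6)

    def test_direct_softplus_value(self):
        # -softplus(-1) - softplus(-1)
        assert js_objective(np.array([1.0]), np.array([-1.0])) == pytest.approx(
            -0.62652, abs=1e-5
        )

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-30, 30), min_size=1, max_size=8))
    def test_never_positive(self, logits):
        f = np.asarray(logits)
        assert js_objective(f, f) <= 1e-12

    def test_softplus_logsigmoid_identity(self):
        # -softplus(-f) == log sigmoid(f), the identity linking the objective
        # to the per-cell log-probability reading
        from scipy.special import log_expit

        f = np.linspace(-20, 20, 101)
        np.testing.assert_allclose(-softplus(-f), log_expit(f), atol=1e-12)


class TestNormalizeScores:
    def test_baseline_maps_to_zero(self):
        sal, total = normalize_scores(np.array([LOG_QUARTER]))
        assert sal[0] == 0.0 and total == 0.0

    def test_perfect_maps_to_one(self):
        sal, _ = normalize_scores(np.array([0.0]))
        assert sal[0] == 1.0

    def test_affine_arithmetic(self):
        sal, _ = normalize_scores(np.array([-0.62652]))
        assert sal[0] == pytest.approx(0.5481, abs=1e-4)

    def test_below_baseline_clipped(self):
        sal, _ = normalize_scores(np.array([LOG_QUARTER - 0.5]))
        assert sal[0] == 0.0

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-3, 0), min_size=1, max_size=20))
    def test_sum_equals_normalized(self, raw):
        sal, total = normalize_scores(np.array(raw))
        assert np.all((sal >= 0) & (sal <= 1))
        assert total == pytest.approx(sal.sum())


class TestBinomialTest:
    def test_all_correct(self):
        assert binomial_test(10, 10) == pytest.approx(2.0**-10)

    def test_none_correct_full_tail(self):
        assert binomial_test(0, 7) == 1.0

    def test_half_correct(self):
        assert binomial_test(5, 10) == pytest.approx(0.6230, abs=1e-4)

    def test_zero_trials(self):
        assert binomial_test(0, 0) == 1.0

    def test_matches_pmf_summation(self):
        # brute-force tail sum over all (k, n <= 20)
        from math import comb

        for n in range(1, 21):
            for k in range(n + 1):
                brute = sum(comb(n, i) for i in range(k, n + 1)) / 2**n
                assert binomial_test(k, n) == pytest.approx(brute, rel=1e-12)

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(1, 200))
    def test_monotone_in_k(self, n):
        ps = [binomial_test(k, n) for k in range(n + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestAdjustPvalues:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            adjust_pvalues(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert adjust_pvalues(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_array_equal(adjust_pvalues(np.ones(5)), np.ones(5))

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_q_at_least_p(self, ps):
        p = np.array(ps)
        q = adjust_pvalues(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0)


class TestTrainGene:
    def test_constant_gene_skipped_at_baseline(self, rng):
        ds = SpatialDataset(counts=np.ones((30, 1)), coords=rng.uniform(0, 1, (30, 2)))
        res = SpatialInformationModel(ds, bin_sizes=(), uncertainty="none").fit(seed=0)
        row = res.scores.iloc[0]
        assert row.skipped
        assert row.normalized_score == 0.0
        assert row.p_value == 1.0

    def test_strong_signal_beats_null(self, half_grid_dataset):
        m = SpatialInformationModel(
            half_grid_dataset, graph_method="grid", bin_sizes=(), uncertainty="none"
        )
        res = m.fit(seed=0)
        row = res.scores.iloc[0]
        assert row.normalized_score > 50
        assert row.p_value < 1e-10
        assert row.accuracy > 0.52

    def test_objective_not_materially_below_baseline(self, null_dataset):
        res = SpatialInformationModel(null_dataset, bin_sizes=()).fit(seed=3)
        assert np.all(res.scores.raw_score >= LOG_QUARTER - 0.05)

    def test_saliency_sums_to_normalized_score(self, half_grid_dataset):
        res = SpatialInformationModel(
            half_grid_dataset, graph_method="grid", bin_sizes=(), uncertainty="none"
        ).fit(seed=0)
        r = res.gene_results[0]
        assert r.normalized_score == pytest.approx(r.saliency.sum())
        assert np.all((r.saliency >= 0) & (r.saliency <= 1))

    def test_saliency_localized_to_informative_region(self, grid30):
        # a hotspot gene: saliency should be higher inside the hotspot
        inside = np.linalg.norm(grid30 - 15, axis=1) < 6
        gene = np.where(inside, 5.0, 0.0)
        ds = SpatialDataset(counts=gene[:, None], coords=grid30)
        res = SpatialInformationModel(ds, graph_method="grid", bin_sizes=(), uncertainty="none").fit(seed=0)
        sal = res.gene_results[0].saliency
        assert sal[inside].mean() > sal[~inside].mean()
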