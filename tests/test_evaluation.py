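import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import ndtr

from corrdiff import (
    CaseData,
    ClassifierModel,
    LabelMap,
    ScalarMap,
    ValidationError,
    binormal_roc,
    binormal_roc_from_moments,
    classify,
    empirical_roc,
    fit_ml_classifier,
    loocv,
    separability,
)


def make_case(case_id, cancer_scores, healthy_scores, seed=0):
    """Assemble a CaseData whose gland holds the given class scores."""
    n_c, n_h = len(cancer_scores), len(healthy_scores)
    n = n_c + n_h
    shape = (n, 1, 1)
    labels = np.zeros(shape, dtype=np.int32)
    values = np.zeros(shape)
    labels[:n_c, 0, 0] = 2
    values[:n_c, 0, 0] = cancer_scores
    labels[n_c:, 0, 0] = 1
    values[n_c:, 0, 0] = healthy_scores
    return CaseData(
        case_id=case_id,
        score_map=ScalarMap(values=values, spacing=(1, 1, 1)),
        labels=LabelMap(labels=labels, spacing=(1, 1, 1)),
    )


class TestBinormalROC:
    def test_closed_form_from_injected_moments(self):
        # mu0=0, sigma0=1, mu1=sqrt(2), sigma1=1 -> Az = Phi(1).
        roc = binormal_roc_from_moments(0.0, 1.0, np.sqrt(2.0), 1.0)
        assert roc.Az == pytest.approx(ndtr(1.0), abs=1e-12)
        assert roc.Az == pytest.approx(0.8413, abs=5e-5)

    def test_az_consistent_with_a_b_identity(self):
        roc = binormal_roc_from_moments(1.0, 2.0, 4.0, 3.0)
        assert roc.Az == pytest.approx(
            ndtr(roc.a / np.sqrt(1 + roc.b**2)), abs=1e-12
        )

    def test_identical_samples_give_half(self):
        scores = [1.0, 2.0, 3.0, 4.0]
        assert binormal_roc(scores, scores).Az == 0.5

    def test_reversed_orientation_gives_below_half(self):
        rng = np.random.default_rng(0)
        low = rng.normal(0, 1, 200)
        high = rng.normal(2, 1, 200)
        assert binormal_roc(low, high).Az < 0.5  # cancer scores lower

    def test_curve_endpoints_and_monotonicity(self):
        roc = binormal_roc_from_moments(0.0, 1.0, 1.5, 2.0)
        curve = roc.curve
        assert tuple(curve[0]) == (0.0, 0.0)
        assert tuple(curve[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve[:, 1]) >= 0)
        assert len(curve) >= 201

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            binormal_roc([1.0, 1.0], [0.0, 1.0])

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            binormal_roc([1.0], [0.0, 1.0])

    def test_large_sample_converges_to_closed_form(self):
        rng = np.random.default_rng(7)
        healthy = rng.normal(0.0, 1.0, 10_000)
        cancer = rng.normal(1.0, 2.0, 10_000)
        expected = ndtr(1.0 / np.sqrt(1 + 4))
        assert binormal_roc(cancer, healthy).Az == pytest.approx(expected, abs=0.01)


class TestEmpiricalROC:
    def test_perfect_separation(self):
        _, auc = empirical_roc([10.0, 11.0], [1.0, 2.0])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        _, auc = empirical_roc([5.0, 5.0], [5.0, 5.0])
        assert auc == 0.5

    def test_hand_enumerated_pair_count(self):
        # cancer {3,5} vs healthy {1,4}: wins (3>1), (5>1), (5>4); loss
        # (3<4) -> 3/4 of pairs.
        _, auc = empirical_roc([3.0, 5.0], [1.0, 4.0])
        assert auc == pytest.approx(0.75)

    def test_agrees_with_binormal_on_gaussian_data(self):
        rng = np.random.default_rng(21)
        healthy = rng.normal(0, 1, 10_000)
        cancer = rng.normal(1.5, 1.2, 10_000)
        _, auc = empirical_roc(cancer, healthy)
        assert auc == pytest.approx(binormal_roc(cancer, healthy).Az, abs=0.02)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        seed=st.integers(0, 10_000),
        scale=st.floats(0.1, 5.0),
        shift=st.floats(-3.0, 3.0),
    )
    def test_invariant_under_strictly_increasing_transform(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        cancer = rng.normal(1, 1, 40)
        healthy = rng.normal(0, 1, 50)

        def transform(x):
            return np.exp(scale * x + shift)

        _, auc = empirical_roc(cancer, healthy)
        _, auc_t = empirical_roc(transform(cancer), transform(healthy))
        assert auc == pytest.approx(auc_t, abs=1e-12)


class TestSeparability:
    def test_identical_distributions_give_zero(self):
        assert separability([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_exact_moment_example(self):
        # means 2 and 0, population variances 1 and 1 -> 4 / 2 = 2.
        assert separability([1.0, 3.0], [-1.0, 1.0]) == pytest.approx(2.0)

    def test_monotone_in_mean_gap_at_fixed_variance(self):
        values = []
        for gap in [0.5, 1.0, 2.0, 4.0]:
            values.append(separability([gap - 1, gap + 1], [-1.0, 1.0]))
        assert values == sorted(values)
        expected = [gap**2 / 2 for gap in [0.5, 1.0, 2.0, 4.0]]
        np.testing.assert_allclose(values, expected, rtol=1e-12)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValidationError):
            separability([1.0, 1.0], [2.0, 2.0])


class TestMLClassifier:
    def test_degenerate_classes_get_sd_floor(self):
        case = make_case("a", [3.0, 3.0, 3.0], [1.0, 1.0, 1.0])
        model = fit_ml_classifier([case])
        assert model.mean_cancer == 3.0
        assert model.mean_healthy == 1.0
        assert model.sd_cancer > 0 and model.sd_healthy > 0

    def test_pooling_duplicate_cases_is_idempotent(self):
        rng = np.random.default_rng(5)
        case = make_case("a", rng.normal(3, 1, 50), rng.normal(1, 1, 80))
        single = fit_ml_classifier([case])
        double = fit_ml_classifier([case, case])
        for attr in ("mean_cancer", "sd_cancer", "mean_healthy", "sd_healthy"):
            assert getattr(double, attr) == pytest.approx(
                getattr(single, attr), rel=1e-12
            )

    def test_estimates_converge_to_generating_parameters(self):
        rng = np.random.default_rng(11)
        n = 100_000
        case = make_case("a", rng.normal(3.0, 0.5, n), rng.normal(1.0, 2.0, n))
        model = fit_ml_classifier([case])
        assert model.mean_cancer == pytest.approx(3.0, abs=3 * 0.5 / np.sqrt(n))
        assert model.mean_healthy == pytest.approx(1.0, abs=3 * 2.0 / np.sqrt(n))
        assert model.sd_cancer == pytest.approx(0.5, rel=0.02)
        assert model.sd_healthy == pytest.approx(2.0, rel=0.02)

    def test_single_class_pool_rejected(self):
        case = make_case("a", [], [1.0, 2.0])
        with pytest.raises(ValidationError, match="both classes"):
            fit_ml_classifier([case])

    def test_equal_sds_put_boundary_at_midpoint(self):
        model = ClassifierModel(
            mean_healthy=1.0, sd_healthy=0.5, mean_cancer=3.0, sd_cancer=0.5
        )
        case = make_case("probe", [2.1, 3.0], [1.9, 1.0])
        prediction, metrics = classify(model, case.score_map, case.labels)
        # 2.1 and 3.0 are nearer 3 -> cancer; 1.9 and 1.0 nearer 1 -> healthy.
        assert metrics.tp == 2 and metrics.tn == 2
        assert metrics.fp == 0 and metrics.fn == 0

    def test_unequal_sds_match_direct_density_comparison(self):
        model = ClassifierModel(
            mean_healthy=0.0, sd_healthy=1.0, mean_cancer=0.0, sd_cancer=3.0
        )
        probes = np.array([-6.0, -2.0, 0.0, 2.0, 6.0])
        case = make_case("probe", probes, [0.1, -0.1])
        prediction, _ = classify(model, case.score_map, case.labels)
        expected = stats.norm.pdf(probes, 0.0, 3.0) > stats.norm.pdf(probes, 0.0, 1.0)
        np.testing.assert_array_equal(prediction[: len(probes), 0, 0], expected)

    def test_shape_mismatch_rejected(self):
        model = ClassifierModel(1.0, 1.0, 3.0, 1.0)
        case = make_case("a", [3.0], [1.0])
        other = make_case("b", [3.0, 3.0], [1.0, 1.0])
        with pytest.raises(ValidationError, match="shape"):
            classify(model, case.score_map, other.labels)


class TestLOOCV:
    def test_identical_separated_cases_score_perfectly(self):
        cases = [
            make_case("a", [10.0, 11.0, 12.0], [0.0, 1.0, 2.0]),
            make_case("b", [10.0, 11.0, 12.0], [0.0, 1.0, 2.0]),
        ]
        per_case, pooled = loocv(cases)
        assert pooled.sensitivity == 1.0
        assert pooled.specificity == 1.0
        assert pooled.accuracy == 1.0

    def test_pooled_counts_are_fold_sums(self):
        rng = np.random.default_rng(3)
        cases = [
            make_case(str(k), rng.normal(2, 1, 30), rng.normal(0, 1, 40), seed=k)
            for k in range(4)
        ]
        per_case, pooled = loocv(cases)
        for attr in ("tp", "fp", "tn", "fn"):
            assert getattr(pooled, attr) == sum(getattr(m, attr) for m in per_case)

    def test_metric_identities_hold_exactly(self):
        rng = np.random.default_rng(9)
        cases = [
            make_case(str(k), rng.normal(2, 1, 25), rng.normal(0, 1, 35))
            for k in range(3)
        ]
        _, pooled = loocv(cases)
        assert pooled.sensitivity == pooled.tp / (pooled.tp + pooled.fn)
        assert pooled.specificity == pooled.tn / (pooled.tn + pooled.fp)
        total = pooled.tp + pooled.fp + pooled.tn + pooled.fn
        assert pooled.accuracy == (pooled.tp + pooled.tn) / total
        lo = min(pooled.sensitivity, pooled.specificity)
        hi = max(pooled.sensitivity, pooled.specificity)
        assert lo <= pooled.accuracy <= hi

    def test_fewer_than_two_cases_rejected(self):
        case = make_case("a", [3.0, 4.0], [1.0, 2.0])
        with pytest.raises(ValidationError, match=">= 2"):
            loocv([case])
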