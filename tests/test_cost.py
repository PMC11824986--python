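import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mkelm import (
    CostMatrix,
    InvalidArgumentError,
    compute_cost_weights,
    evaluate,
    fit_celm,
    make_cost_matrix,
    min_risk_decide,
    relative_performance,
    scores_to_posteriors,
    zero_one_costs,
)
from mkelm.linalg import random_map
from mkelm.models import one_hot_targets, predict_labels, predict_scores

from _oracles import weighted_ridge_lstsq


class TestPosteriors:
    def test_zero_scores_give_uniform_posteriors(self):
        assert np.allclose(scores_to_posteriors([[0.0, 0.0, 0.0]]), 1 / 3)

    def test_extreme_scores(self):
        p = scores_to_posteriors([[10.0, -10.0]])
        assert p[0, 0] == pytest.approx(0.99995, abs=1e-4)
        assert p[0, 1] == pytest.approx(4.54e-5, rel=0.02)

    def test_rows_sum_to_one(self, rng):
        p = scores_to_posteriors(rng.normal(scale=50, size=(500, 4)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(p >= 0)


class TestMinRiskDecide:
    def test_symmetric_cost_reduces_to_map(self):
        cost = CostMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), np.array([0, 1]))
        assert min_risk_decide([[0.9, 0.1]], cost)[0] == 0

    def test_asymmetric_cost_overrides_map(self):
        # risks: predict 0 -> 0.3*10 = 3.0, predict 1 -> 0.7*1 = 0.7
        cost = CostMatrix(np.array([[0.0, 1.0], [10.0, 0.0]]), np.array([0, 1]))
        assert min_risk_decide([[0.7, 0.3]], cost)[0] == 1

    def test_tie_breaks_to_lowest_class(self):
        cost = CostMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), np.array([0, 1]))
        assert min_risk_decide([[0.5, 0.5]], cost)[0] == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_risk_optimality_and_invariances(self, seed):
        r = np.random.default_rng(seed)
        m = int(r.integers(2, 7))
        post = r.dirichlet(np.ones(m), size=20)
        costs = r.uniform(0, 10, size=(m, m))
        np.fill_diagonal(costs, 0.0)
        costs.flat[1] += 1e-6  # ensure some off-diagonal cost
        cm = CostMatrix(costs, np.arange(m))
        decided = min_risk_decide(post, cm)
        risks = post @ costs
        assert np.all(risks[np.arange(20), decided] <= risks.min(axis=1) + 1e-12)
        # positive scaling never changes decisions
        scaled = CostMatrix(costs * 7.3, np.arange(m))
        assert np.array_equal(min_risk_decide(post, scaled), decided)
        # 0-1 costs reduce to argmax
        assert np.array_equal(
            min_risk_decide(post, zero_one_costs(m)), np.argmax(post, axis=1)
        )


class TestMakeCostMatrix:
    @pytest.mark.parametrize("family,maxval", [("uniform_range", 20), ("type_a", 10)])
    def test_uniform_families_ranges(self, family, maxval):
        cm = make_cost_matrix(4, family, max_cost=20, seed=3)
        off = cm.costs[~np.eye(4, dtype=bool)]
        assert np.all((off >= 1) & (off <= maxval))
        assert np.all(off == np.round(off))
        assert np.all(np.diag(cm.costs) == 0)

    def test_type_b_constant_rows(self):
        cm = make_cost_matrix(5, "type_b", seed=1)
        for i in range(5):
            row = np.delete(cm.costs[i], i)
            assert np.all(row == row[0])
            assert 1 <= row[0] <= 10

    def test_type_c_inverse_frequency(self):
        cm = make_cost_matrix(3, "type_c", seed=0, class_counts=[100, 50, 10])
        off = cm.costs[~np.eye(3, dtype=bool)]
        assert off.max() == pytest.approx(10.0)
        # rarest class carries the maximal misclassification cost
        assert cm.costs[2, 0] == pytest.approx(10.0)
        assert cm.costs[0, 1] == pytest.approx(1.0)

    def test_type_c_requires_counts(self):
        with pytest.raises(InvalidArgumentError):
            make_cost_matrix(3, "type_c", seed=0)

    def test_deterministic_and_m_validation(self):
        a = make_cost_matrix(3, "uniform_range", seed=9)
        b = make_cost_matrix(3, "uniform_range", seed=9)
        assert np.array_equal(a.costs, b.costs)
        with pytest.raises(InvalidArgumentError):
            make_cost_matrix(1, "type_a")


class TestCostWeights:
    def test_balanced_labels_give_unit_weights(self):
        w = compute_cost_weights([0, 0, 1, 1], None, "class_balance")
        assert np.allclose(w, 1.0)

    def test_imbalanced_class_balance(self):
        y = np.repeat([0, 1], [90, 10])
        w = compute_cost_weights(y, None, "class_balance")
        assert np.allclose(w[y == 0], 10 / 90)
        assert np.allclose(w[y == 1], 1.0)

    def test_row_sum_weights(self):
        cm = CostMatrix(np.array([[0.0, 1.0], [10.0, 0.0]]), np.array([0, 1]))
        w = compute_cost_weights([0, 1, 1], cm, "row_sum")
        assert np.allclose(w, [1.0, 10.0, 10.0])

    def test_helm_weights_positive(self):
        y = np.repeat([0, 1, 2], [80, 15, 5])
        w = compute_cost_weights(y, None, "helm")
        assert np.all(w > 0)


class TestCelm:
    def test_unit_weights_reduce_to_plain_ridge(self, rng):
        from mkelm import fit_elm_classifier

        X = rng.normal(size=(30, 3))
        y = rng.integers(0, 2, size=30)
        cm = zero_one_costs(2)  # row sums are all 1
        a = fit_celm(X, y, cm, L=12, C=5.0, seed=8)
        b = fit_elm_classifier(X, y, L=12, C=5.0, seed=8)
        assert np.allclose(a.beta, b.beta, atol=1e-10)

    def test_matches_weighted_least_squares_oracle(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.integers(0, 2, size=20)
        cm = CostMatrix(np.array([[0.0, 3.0], [7.0, 0.0]]), np.array([0, 1]))
        model = fit_celm(X, y, cm, L=10, C=4.0, seed=2)
        H = random_map(model.hidden_layer, X)
        T = one_hot_targets(y, model.classes, "plus_minus_one")
        w = compute_cost_weights(y, cm, "row_sum")
        assert np.allclose(model.beta, weighted_ridge_lstsq(H, T, w, 4.0), atol=1e-6)

    def test_upweighting_never_hurts_weighted_class_recall(self):
        # overlapping clusters; heavy cost on class 1 errors should pull
        # its training recall up relative to the unweighted fit
        from mkelm import SyntheticSpec, fit_elm_classifier, generate_classification_data

        diffs = []
        for seed in range(10):
            X, y = generate_classification_data(
                SyntheticSpec(120, 3, 2, None, 1.5, 1.0, seed)
            )
            cm = CostMatrix(np.array([[0.0, 1.0], [20.0, 0.0]]), np.array([0, 1]))
            weighted = fit_celm(X, y, cm, L=60, C=10.0, seed=seed)
            plain = fit_elm_classifier(X, y, L=60, C=10.0, seed=seed)

            def recall(clf):
                pred = predict_labels(clf, X)
                return np.mean(pred[y == 1] == 1)

            diffs.append(recall(weighted) - recall(plain))
        assert np.mean(diffs) >= 0


class TestEvaluation:
    def test_perfect_predictions(self):
        cm = make_cost_matrix(3, "type_a", seed=0)
        rep = evaluate([0, 1, 2, 1], [0, 1, 2, 1], cm)
        assert rep.acc == 1.0 and rep.total_cost == 0.0

    def test_hand_tallied_costs(self):
        costs = np.array([[0.0, 3.0], [7.0, 0.0]])
        cm = CostMatrix(costs, np.array([0, 1]))
        y = np.array([0] * 5 + [1] * 5)
        pred = y.copy()
        pred[0] = 1   # true 0 -> 1, cost 3
        pred[5] = 0   # true 1 -> 0, cost 7
        rep = evaluate(y, pred, cm)
        assert rep.acc == pytest.approx(0.8)
        assert rep.total_cost == pytest.approx(10.0)
        assert rep.confusion.sum() == 10

    def test_unknown_label_rejected(self):
        cm = zero_one_costs(2)
        with pytest.raises(InvalidArgumentError):
            evaluate([0, 1], [0, 5], cm)


class TestRelativePerformance:
    def test_worst_method_is_one(self):
        assert relative_performance([50.0, 100.0]) == [0.5, 1.0]
        assert relative_performance([42.0]) == [1.0]

    def test_all_zero_costs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            relative_performance([0.0, 0.0])
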