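"""Attribution oracles: closed forms, brute-force Shapley, completeness."""

import itertools
import math

import numpy as np
import pytest

from advint import CellTypeMLP
from advint.errors import ParameterError
from advint.interpret import (
    activation_maximization,
    deeplift_rescale,
    expected_gradients,
    kernel_shap,
    lime_tabular,
    per_class_importance,
    saliency,
)


def _linear_model(w, b=None, n_classes=2):
    """Model whose class-0 score is w.x (+b); class 1 mirrors it."""
    w = np.asarray(w, dtype=np.float64)
    model = CellTypeMLP(hidden_layer_sizes=())
    model.classes_ = np.array([f"k{i}" for i in range(n_classes)])
    model.n_features_in_ = w.size
    W = np.zeros((w.size, n_classes))
    W[:, 0] = w
    if n_classes > 1:
        W[:, 1] = -w
    model.coefs_ = [W]
    model.intercepts_ = [np.zeros(n_classes) if b is None else b]
    return model


class TestSaliency:
    def test_linear_model_scores_equal_weights_everywhere(self):
        w = np.array([2.0, -1.0, 0.5])
        model = _linear_model(w)
        for x in (np.zeros(3), np.array([5.0, -3.0, 1.0])):
            np.testing.assert_allclose(saliency(model, x, 0), w)

    def test_constant_model_zero_scores(self):
        model = _linear_model(np.zeros(4), b=np.array([3.0, 3.0]))
        np.testing.assert_array_equal(saliency(model, np.ones(4), 0), 0.0)

    def test_matches_finite_differences_on_random_net(self, tiny_model):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        s = saliency(tiny_model, x, 2)
        h = 1e-6
        for j in range(12):
            e = np.zeros(12)
            e[j] = h
            fd = (
                tiny_model.decision_function((x + e)[None])[0, 2]
                - tiny_model.decision_function((x - e)[None])[0, 2]
            ) / (2 * h)
            assert abs(fd - s[j]) / max(abs(fd), abs(s[j]), 1e-8) < 1e-4


class TestActivationMaximization:
    def test_linear_logit_maximizer_on_sphere(self):
        w = np.array([3.0, -4.0])  # maximizer is r * w / ||w||
        model = _linear_model(w)
        x_star, _ = activation_maximization(
            model, 0, constraint_radius=2.0, n_steps=300, step_size=1.0, seed=1
        )
        np.testing.assert_allclose(x_star, 2.0 * w / 5.0, atol=1e-3)

    def test_objective_trace_monotone(self, tiny_model):
        _, trace = activation_maximization(tiny_model, 1, n_steps=100, seed=2)
        assert np.all(np.diff(trace) >= 0)

    def test_beats_random_search_on_toy_net(self, tiny_model):
        rng = np.random.default_rng(3)
        r = 3.0
        x_star, _ = activation_maximization(
            tiny_model, 0, constraint_radius=r, n_steps=400, step_size=0.5, seed=4
        )
        best = max(
            float(tiny_model.decision_function(v[None])[0, 0])
            for v in (
                u * r / np.linalg.norm(u)
                for u in rng.normal(size=(1000, 12))
            )
        )
        got = float(tiny_model.decision_function(x_star[None])[0, 0])
        assert got >= best - 1e-2

    def test_bad_radius_rejected(self, tiny_model):
        with pytest.raises(ParameterError):
            activation_maximization(tiny_model, 0, constraint_radius=0.0)


class TestDeepLIFT:
    def test_linear_completeness(self):
        w = np.array([1.5, -2.0, 0.25])
        model = _linear_model(w)
        x, ref = np.array([1.0, 2.0, 3.0]), np.array([0.5, 0.0, -1.0])
        c = deeplift_rescale(model, x, ref, 0)
        np.testing.assert_allclose(c, w * (x - ref), rtol=1e-12)

    def test_input_equal_baseline_gives_zero(self, tiny_model):
        x = np.random.default_rng(5).normal(size=12)
        np.testing.assert_array_equal(deeplift_rescale(tiny_model, x, x, 0), 0.0)

    def test_hand_computed_relu_rescale_chain(self):
        """One ReLU unit, hand-chosen weights: multiplier is
        (relu(z)-relu(z'))/(z-z') chained through both affine layers."""
        model = CellTypeMLP(hidden_layer_sizes=(1,))
        model.classes_ = np.array(["a", "b"])
        model.n_features_in_ = 2
        model.coefs_ = [np.array([[1.0], [2.0]]), np.array([[3.0, 0.0]])]
        model.intercepts_ = [np.array([-2.0]), np.zeros(2)]
        x, ref = np.array([2.0, 1.0]), np.array([0.0, 0.0])
        # z = 1*2 + 2*1 - 2 = 2 -> relu 2 ; z' = -2 -> relu 0
        # multiplier = (2-0)/(2-(-2)) = 0.5 ; output weight 3
        # contribution_i = (x_i - ref_i) * w_i * 0.5 * 3
        expected = np.array([2.0 * 1.0, 1.0 * 2.0]) * 0.5 * 3.0
        got = deeplift_rescale(model, x, ref, 0)
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_completeness_on_random_net(self, tiny_model):
        rng = np.random.default_rng(6)
        x, ref = rng.normal(size=12), rng.normal(size=12)
        for k in range(3):
            c = deeplift_rescale(tiny_model, x, ref, k)
            fx = tiny_model.decision_function(x[None])[0, k]
            fr = tiny_model.decision_function(ref[None])[0, k]
            assert abs(c.sum() - (fx - fr)) < 1e-5


class TestExpectedGradients:
    def test_linear_model_exact_per_sample(self):
        w = np.array([1.0, -2.0, 3.0])
        model = _linear_model(w)
        x = np.array([2.0, 2.0, 2.0])
        baselines = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]])
        got = expected_gradients(model, x, baselines, 0, n_samples=400, seed=7)
        # per-sample value is w*(x - x'); mean over the two baselines
        expected = w * (x - baselines.mean(axis=0))
        np.testing.assert_allclose(got, expected, rtol=0.15)

    def test_degenerate_single_baseline_t1_reduces_to_gradient_times_delta(
        self, tiny_model
    ):
        rng = np.random.default_rng(8)
        x, ref = rng.normal(size=12), rng.normal(size=12)
        got = expected_gradients(
            tiny_model, x, ref[None], 1, n_samples=1, seed=0, t_values=np.array([1.0])
        )
        grad = tiny_model.gradient_score(x[None], 1)[0]
        np.testing.assert_allclose(got, grad * (x - ref), rtol=1e-10)

    def test_monte_carlo_error_shrinks_with_samples(self, tiny_model):
        rng = np.random.default_rng(9)
        x = rng.normal(size=12)
        ref = rng.normal(size=(30, 12))

        def spread(n):
            reps = [
                expected_gradients(tiny_model, x, ref, 0, n_samples=n, seed=s)
                for s in range(10)
            ]
            return np.std(np.stack(reps), axis=0).mean()

        assert spread(256) < spread(16) / 2.0  # ~1/sqrt(n) scaling

    def test_empty_baseline_pool_rejected(self, tiny_model):
        with pytest.raises(ParameterError):
            expected_gradients(
                tiny_model, np.zeros(12), np.zeros((0, 12)), 0, n_samples=5
            )


def _exact_shapley(f, x, ref):
    """Brute-force Shapley values by enumerating all subsets."""
    d = x.size
    phi = np.zeros(d)
    for i in range(d):
        others = [j for j in range(d) if j != i]
        for size in range(d):
            for S in itertools.combinations(others, size):
                weight = (
                    math.factorial(size) * math.factorial(d - size - 1)
                ) / math.factorial(d)
                z = ref.copy()
                z[list(S)] = x[list(S)]
                without = f(z[None])[0]
                z[i] = x[i]
                with_i = f(z[None])[0]
                phi[i] += weight * (with_i - without)
    return phi


class TestKernelShap:
    def test_additive_model_exact(self):
        """f(x) = sum_i f_i(x_i): phi_i = f_i(x_i) - f_i(ref_i)."""
        w = np.array([2.0, -3.0, 0.5, 1.0])
        model = _linear_model(w)
        f = lambda Z: model.decision_function(Z)[:, 0]
        x, ref = np.array([1.0, 2.0, -1.0, 0.0]), np.zeros(4)
        phi = kernel_shap(f, x, ref, exhaustive=True)
        np.testing.assert_allclose(phi, w * x, atol=1e-8)

    def test_matches_exhaustive_shapley_enumeration(self):
        rng = np.random.default_rng(10)
        d = 8
        X = rng.normal(size=(60, d))
        y = np.array(["a", "b"] * 30)
        net = CellTypeMLP(hidden_layer_sizes=(6,), epochs=10, random_state=1).fit(X, y)
        f = lambda Z: net.decision_function(Z)[:, 0]
        x8, ref8 = rng.normal(size=d), rng.normal(size=d)
        phi = kernel_shap(f, x8, ref8, exhaustive=True)
        oracle = _exact_shapley(f, x8, ref8)
        np.testing.assert_allclose(phi, oracle, atol=1e-6)

    def test_completeness_with_sampling(self, tiny_model):
        rng = np.random.default_rng(11)
        x, ref = rng.normal(size=12), rng.normal(size=12)
        f = lambda Z: tiny_model.decision_function(Z)[:, 1]
        phi = kernel_shap(f, x, ref, n_coalitions=300, seed=3)
        assert abs(phi.sum() - (f(x[None])[0] - f(ref[None])[0])) < 1e-6

    def test_too_few_coalitions_rejected(self, tiny_model):
        f = lambda Z: tiny_model.decision_function(Z)[:, 0]
        with pytest.raises(ParameterError):
            kernel_shap(f, np.zeros(12), np.zeros(12), n_coalitions=5)


class TestLime:
    def test_linear_coefficient_recovery(self):
        w = np.random.default_rng(12).normal(size=10)
        model = _linear_model(w)
        f = lambda Z: model.decision_function(Z)[:, 0]
        coef = lime_tabular(
            f, np.zeros(10), n_perturbations=3000, n_features_kept=10, seed=4
        )
        cos = coef @ w / (np.linalg.norm(coef) * np.linalg.norm(w))
        assert cos > 0.99

    def test_sparsity_respected(self):
        w = np.random.default_rng(13).normal(size=20)
        model = _linear_model(w)
        f = lambda Z: model.decision_function(Z)[:, 0]
        coef = lime_tabular(f, np.zeros(20), n_features_kept=5, seed=5)
        assert np.count_nonzero(coef) <= 5

    def test_constant_model_all_zero(self):
        model = _linear_model(np.zeros(6), b=np.array([2.0, 2.0]))
        f = lambda Z: model.decision_function(Z)[:, 0]
        coef = lime_tabular(f, np.ones(6), n_features_kept=6, seed=6)
        np.testing.assert_allclose(coef, 0.0, atol=1e-8)

    def test_seeded_determinism(self, tiny_model):
        f = lambda Z: tiny_model.decision_function(Z)[:, 0]
        x = np.random.default_rng(14).normal(size=12)
        a = lime_tabular(f, x, n_features_kept=6, seed=7)
        b = lime_tabular(f, x, n_features_kept=6, seed=7)
        np.testing.assert_array_equal(a, b)


class TestPerClassImportance:
    def test_single_cell_class_equals_absolute_attribution(self):
        scores = np.array([[1.0, -2.0], [5.0, 5.0]])
        mat = per_class_importance(
            scores,
            labels=np.array(["a", "b"]),
            correct=np.array([True, True]),
            gene_ids=["g1", "g2"],
            class_names=["a", "b"],
        )
        np.testing.assert_allclose(mat.scores["a"], [1.0, 2.0])

    def test_mean_of_absolutes_sign_rule(self):
        scores = np.array([[3.0, 0.0], [-3.0, 0.0]])
        mat = per_class_importance(
            scores,
            labels=np.array(["a", "a"]),
            correct=np.array([True, True]),
            gene_ids=["g1", "g2"],
            class_names=["a"],
        )
        assert mat.scores.loc["g1", "a"] == 3.0

    def test_matches_brute_force_group_by(self):
        rng = np.random.default_rng(15)
        scores = rng.normal(size=(5, 3))
        labels = np.array(["a", "b", "a", "b", "a"])
        correct = np.array([True, True, False, True, True])
        mat = per_class_importance(
            scores, labels, correct, ["g1", "g2", "g3"], ["a", "b"]
        )
        for cls in ("a", "b"):
            mask = (labels == cls) & correct
            np.testing.assert_allclose(
                mat.scores[cls].to_numpy(), np.abs(scores[mask]).mean(axis=0)
            )

    def test_fallback_when_no_correct_cells(self):
        scores = np.array([[2.0], [4.0]])
        mat = per_class_importance(
            scores,
            labels=np.array(["a", "a"]),
            correct=np.array([False, False]),
            gene_ids=["g1"],
            class_names=["a"],
        )
        assert mat.scores.loc["g1", "a"] == 3.0


class TestLinearCrossMethodConsistency:
    def test_all_methods_rank_like_absolute_weights(self):
        """On a purely linear score every method's importance ranking
        reduces to |w| (up to Monte-Carlo noise)."""
        rng = np.random.default_rng(16)
        w = np.array([4.0, -3.0, 2.0, -1.0, 0.5, 0.1])
        model = _linear_model(w)
        f = lambda Z: model.decision_function(Z)[:, 0]
        x = rng.normal(size=6)
        ref = np.zeros(6)
        true_rank = np.argsort(-np.abs(w), kind="stable")

        sal = np.abs(saliency(model, x, 0))
        am, _ = activation_maximization(
            model, 0, constraint_radius=1.0, n_steps=300, step_size=0.5, seed=1
        )
        rankings = {
            "saliency": sal,
            "actmax": np.abs(am),
        }
        for name, scores in rankings.items():
            np.testing.assert_array_equal(
                np.argsort(-scores, kind="stable"), true_rank, err_msg=name
            )
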