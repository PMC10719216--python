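"""Attack contracts: closed forms, projection bounds, augmentation, sweep."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import advint
from advint import CellTypeMLP
from advint.attacks import (
    AttackConfig,
    adversarial_train,
    build_adversarial_training_set,
    epsilon_sweep,
    fgsm,
    neighborhood_preservation,
    pgd,
)
from advint.errors import DimensionError, ParameterError

from conftest import make_adata


def _logistic_model(rng, d=6):
    model = CellTypeMLP(hidden_layer_sizes=())
    model.classes_ = np.array(["a", "b"])
    model.n_features_in_ = d
    model.coefs_ = [rng.normal(size=(d, 2))]
    model.intercepts_ = [rng.normal(size=2)]
    return model


class TestFGSM:
    def test_zero_epsilon_is_identity(self, tiny_model):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 12))
        y = np.array(["a", "b", "c", "a"])
        np.testing.assert_array_equal(fgsm(tiny_model, X, y, 0.0), X)

    def test_logistic_closed_form_perturbation(self):
        """Two-class softmax: dL/dx = (p - onehot) W^T, so the step is
        eps * sign((p_b - y_b)(w_b - w_a)) rowwise."""
        rng = np.random.default_rng(1)
        model = _logistic_model(rng)
        X = rng.normal(size=(5, 6))
        y = np.array(["a", "b", "a", "b", "a"])
        p = model.predict_proba(X)
        onehot = np.eye(2)[[0, 1, 0, 1, 0]]
        grad = (p - onehot) @ model.coefs_[0].T
        np.testing.assert_array_equal(
            fgsm(model, X, y, 0.3), X + 0.3 * np.sign(grad)
        )

    def test_negative_epsilon_rejected(self, tiny_model):
        with pytest.raises(ParameterError):
            fgsm(tiny_model, np.zeros((1, 12)), ["a"], -0.1)

    @settings(max_examples=20, deadline=None)
    @given(eps=st.floats(0.01, 3.0), seed=st.integers(0, 100))
    def test_linf_bound_property(self, tiny_model, eps, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(3, 12))
        y = np.array(["a", "b", "c"])
        assert np.abs(fgsm(tiny_model, X, y, eps) - X).max() <= eps + 1e-12


class TestPGD:
    def test_single_step_alpha_eps_equals_fgsm_bitwise(self, tiny_model):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 12))
        y = np.array(["a", "b", "c"] * 2)
        a = fgsm(tiny_model, X, y, 0.7)
        b = pgd(tiny_model, X, y, 0.7, alpha=0.7, n_iter=1)
        np.testing.assert_array_equal(a, b)

    def test_zero_epsilon_returns_input(self, tiny_model):
        X = np.random.default_rng(3).normal(size=(2, 12))
        y = np.array(["a", "b"])
        np.testing.assert_array_equal(pgd(tiny_model, X, y, 0.0, n_iter=5), X)

    def test_projection_property_many_iterates(self, tiny_model):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 12))
        y = np.array(["a", "b", "c", "a"] * 5)
        X_adv = pgd(tiny_model, X, y, 0.5, alpha=0.3, n_iter=10)
        assert np.abs(X_adv - X).max() <= 0.5 + 1e-12


class TestAugmentation:
    def test_doubles_rows_and_marks_provenance(self, small_split, small_model):
        train, _, _ = small_split
        aug = build_adversarial_training_set(
            train, small_model, AttackConfig(epsilon=0.5)
        )
        assert aug.n_obs == 2 * train.n_obs
        assert (aug.obs["provenance"] == "original").sum() == train.n_obs
        assert (aug.obs["provenance"] == "adversarial").sum() == train.n_obs

    def test_adversarial_half_keeps_source_labels_in_order(
        self, small_split, small_model
    ):
        train, _, _ = small_split
        aug = build_adversarial_training_set(
            train, small_model, AttackConfig(epsilon=0.5)
        )
        n = train.n_obs
        orig = aug.obs["cell_type"].to_numpy()[:n]
        adv = aug.obs["cell_type"].to_numpy()[n:]
        np.testing.assert_array_equal(orig, adv)

    def test_adversarial_rows_within_epsilon(self, small_split, small_model):
        train, _, _ = small_split
        aug = build_adversarial_training_set(
            train, small_model, AttackConfig(epsilon=0.5)
        )
        n = train.n_obs
        X = np.asarray(aug.X)
        assert np.abs(X[n:] - X[:n]).max() <= 0.5 + 1e-12

    def test_feature_mismatch_raises(self, small_model):
        bad = make_adata(np.ones((4, 3)), labels=["a", "b", "a", "b"])
        with pytest.raises(DimensionError):
            build_adversarial_training_set(bad, small_model, AttackConfig())


class TestNeighborhoodPreservation:
    def test_identity_scores_one(self):
        X = np.random.default_rng(5).normal(size=(30, 4))
        assert neighborhood_preservation(X, X, 5) == 1.0

    def test_random_destruction_near_chance(self):
        rng = np.random.default_rng(6)
        n, k = 300, 10
        X = rng.normal(size=(n, 8))
        X_noise = rng.normal(size=(n, 8))  # independent: neighborhoods random
        score = neighborhood_preservation(X, X_noise, k)
        # expected Jaccard for two random k-sets from n-1 candidates:
        # E|A&B| ~ k^2/(n-1); J ~ E|A&B| / (2k - E|A&B|)
        inter = k * k / (n - 1)
        expected = inter / (2 * k - inter)
        assert score < 3 * expected + 0.02

    def test_five_point_configuration_matches_knn_enumeration(self):
        # two tight pairs plus a fifth point that crosses clusters, k=2;
        # the expected score is enumerated independently below
        x = np.array([[0.0], [0.1], [10.0], [10.1], [0.2]])
        x_adv = x.copy()
        x_adv[4] = 9.9
        score = neighborhood_preservation(x, x_adv, 2)

        def brute(data):
            sets = []
            for i in range(5):
                d = np.abs(data - data[i]).ravel()
                d[i] = np.inf
                sets.append(set(np.argsort(d, kind="stable")[:2]))
            return sets

        b, a = brute(x), brute(x_adv)
        expected = np.mean(
            [len(b[i] & a[i]) / len(b[i] | a[i]) for i in range(5)]
        )
        assert score == pytest.approx(expected)

    def test_k_validation(self):
        X = np.zeros((5, 2))
        with pytest.raises(ParameterError):
            neighborhood_preservation(X, X, 0)
        with pytest.raises(ParameterError):
            neighborhood_preservation(X, X, 5)


class TestAdversarialTraining:
    def test_zero_epsilon_matches_duplicated_standard_training(self, small_split):
        """Degenerate attack: augmentation adds exact copies, so accuracy is
        statistically indistinguishable from standard training."""
        train, test, _ = small_split
        std = advint.train_classifier(train, arch=(32,), epochs=15, seed=2)
        rob = adversarial_train(
            train, arch=(32,), attack=AttackConfig(epsilon=0.0),
            mode="static", epochs=15, seed=2,
        )
        a = advint.evaluate(std, test).accuracy
        b = advint.evaluate(rob, test).accuracy
        assert abs(a - b) < 0.1

    def test_unknown_mode_rejected(self, small_split):
        train, _, _ = small_split
        with pytest.raises(ParameterError):
            adversarial_train(train, mode="sometimes")


class TestSweep:
    def test_zero_entry_clean_accuracy_and_full_preservation(
        self, small_split, small_model
    ):
        _, test, _ = small_split
        curve = epsilon_sweep(small_model, test, [0.0, 0.5], k_neighbors=5)
        assert curve.attacked_accuracy[0] == pytest.approx(curve.clean_accuracy)
        assert curve.preservation[0] == 1.0

    def test_accuracy_trends_down_in_epsilon(self, small_split, small_model):
        from scipy.stats import spearmanr

        _, test, _ = small_split
        grid = [0.0, 0.2, 0.5, 1.0, 2.0]
        curve = epsilon_sweep(small_model, test, grid, k_neighbors=5)
        rho, _ = spearmanr(grid, curve.attacked_accuracy)
        assert rho < 0

    def test_empty_or_unsorted_grid_rejected(self, small_split, small_model):
        _, test, _ = small_split
        with pytest.raises(ParameterError):
            epsilon_sweep(small_model, test, [])
        with pytest.raises(ParameterError):
            epsilon_sweep(small_model, test, [1.0, 0.5])
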