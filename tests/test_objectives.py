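"""Losses, regularizers and metrics, checked against closed forms and
independent oracles (finite differences, confusion-matrix recalls,
scikit-learn's balanced accuracy)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import balanced_accuracy_score

from cicnet import (
    LossWeights,
    balanced_accuracy,
    classification_report,
    contractive_penalty,
    cosine_classification_loss,
    kl_gaussian,
    mse,
    subtype_accuracy,
    total_loss,
)

from .conftest import finite_difference_jacobian_sq, toy_cae


class TestMse:
    def test_zero_for_identical_inputs(self):
        x = np.random.default_rng(0).random((3, 4))
        assert mse(x, x) == 0.0

    def test_known_values(self):
        assert mse(np.array([0.0, 0.0]), np.array([1.0, 1.0])) == 1.0
        assert mse(np.array([0.0, 2.0]), np.array([0.0, 0.0])) == 2.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse(np.ones(3), np.ones(4))


class TestCosineLoss:
    def test_perfect_prediction_scores_zero(self):
        t = np.eye(3)
        assert cosine_classification_loss(t, t) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_prediction_scores_one(self):
        t = np.array([[1.0, 0.0]])
        p = np.array([[0.0, 1.0]])
        assert cosine_classification_loss(t, p) == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [2, 5, 10, 34])
    def test_uniform_prediction_closed_form(self, k):
        t = np.zeros((1, k))
        t[0, 0] = 1.0
        p = np.full((1, k), 1.0 / k)
        expected = 1.0 - 1.0 / np.sqrt(k)
        assert cosine_classification_loss(t, p) == pytest.approx(expected, rel=1e-12)

    def test_zero_norm_row_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cosine_classification_loss(np.array([[0.0, 0.0]]), np.array([[0.5, 0.5]]))


class TestContractivePenalty:
    def test_identity_encoder_penalty_equals_input_dim(self):
        # a single linear "layer" acting as identity: BN frozen to identity,
        # weight = I, so the Jacobian is the d x d identity
        from cicnet.networks import BN_EPS

        model = toy_cae(n_in=4, encoder_units=(4,), cic_dim=4, activation="linear",
                        randomize_stats=False)
        for k in model.running:
            if k.endswith("var"):
                model.running[k] = np.full_like(model.running[k], 1.0 - BN_EPS)
            else:
                model.running[k][:] = 0.0
        model.params["enc0_W"].data = np.eye(4)
        model.params["enc0_b"].data[:] = 0.0
        model.params["cic_W"].data = np.eye(4)
        model.params["cic_b"].data[:] = 0.0
        X = np.random.default_rng(0).normal(size=(3, 4))
        assert contractive_penalty(model, X) == pytest.approx(4.0, rel=1e-9)

    def test_linear_encoder_penalty_is_frobenius_norm_of_weight_product(self):
        from cicnet.networks import BN_EPS

        model = toy_cae(activation="linear", randomize_stats=False)
        for k in model.running:
            if k.endswith("var"):
                model.running[k] = np.full_like(model.running[k], 1.0 - BN_EPS)
            else:
                model.running[k][:] = 0.0
        W = (
            model.params["enc0_W"].data
            @ model.params["enc1_W"].data
            @ model.params["cic_W"].data
        )
        X = np.random.default_rng(1).normal(size=(2, 5))
        assert contractive_penalty(model, X) == pytest.approx((W**2).sum(), rel=1e-9)

    @pytest.mark.parametrize(
        "activation,units",
        [
            ("softplus", (7, 6)),
            ("softplus", (6,)),
            ("relu", (8, 6)),
            ("linear", (7, 5, 4)),
            ("softplus", (9, 7, 5)),
        ],
    )
    def test_matches_finite_difference_oracle(self, activation, units):
        model = toy_cae(n_in=5, encoder_units=units, cic_dim=3, activation=activation, seed=3)
        rng = np.random.default_rng(17)
        X = rng.normal(size=(4, 5))
        if activation == "relu":
            X = np.abs(X) + 0.5  # keep away from the relu kink
        analytic = contractive_penalty(model, X)
        fd = finite_difference_jacobian_sq(model, X)
        assert analytic == pytest.approx(fd, rel=1e-4)

    def test_rejected_for_variational_kinds(self):
        from cicnet import ArchitectureConfig, build_model

        arch = ArchitectureConfig(kind="VAE", dropout_kind="none", dropout_rate=0.0)
        model = build_model(arch, 30, 5, 3, 4, seed=0)
        with pytest.raises(ValueError, match="CAE"):
            contractive_penalty(model, np.ones((2, 30)))


class TestKlGaussian:
    def test_standard_normal_scores_zero(self):
        assert kl_gaussian(np.zeros((1, 3)), np.zeros((1, 3))) == 0.0

    def test_unit_mean_shift_scores_half(self):
        assert kl_gaussian(np.array([[1.0]]), np.array([[0.0]])) == pytest.approx(0.5)

    def test_matches_analytic_formula_on_random_draws(self):
        rng = np.random.default_rng(2)
        mu = rng.normal(size=(100, 8))
        logvar = rng.normal(scale=0.8, size=(100, 8))
        expected = 0.5 * (np.exp(logvar) + mu**2 - 1.0 - logvar).sum(axis=1).mean()
        assert kl_gaussian(mu, logvar) == pytest.approx(expected, rel=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_nonnegative_for_any_input(self, seed):
        rng = np.random.default_rng(seed)
        mu = rng.normal(scale=2.0, size=(5, 4))
        logvar = rng.normal(scale=2.0, size=(5, 4))
        assert kl_gaussian(mu, logvar) >= 0.0

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            kl_gaussian(np.array([[np.nan]]), np.array([[0.0]]))


class TestTotalLoss:
    def test_weighted_sum_with_default_weights(self):
        bd = total_loss(
            mrna_mse=0.01,
            mirna_mse=0.02,
            tissue_cos=0.2,
            disease_cos=0.4,
            weights=LossWeights(lambda_contractive=0.0),
            kind="CAE",
            contractive=0.0,
        )
        assert bd.total == pytest.approx(0.5 * 0.2 + 0.5 * 0.4 + 1e-3 * 0.01 + 1e-3 * 0.02)
        assert bd.total == pytest.approx(0.30003)

    def test_all_zero_components_give_zero(self):
        bd = total_loss(0, 0, 0, 0, LossWeights(), "CAE", contractive=0)
        assert bd.total == 0.0

    def test_zero_weight_regularizers_do_not_contribute(self):
        w = LossWeights(lambda_contractive=0.0, kl_weight=0.0)
        a = total_loss(0.1, 0.1, 0.1, 0.1, w, "CAE", contractive=123.0)
        b = total_loss(0.1, 0.1, 0.1, 0.1, w, "CAE", contractive=0.0)
        assert a.total == b.total

    def test_linear_in_each_component(self):
        w = LossWeights(lambda_contractive=0.3, kl_weight=0.0)
        one = total_loss(0.1, 0.2, 0.3, 0.4, w, "DropoutCAE", contractive=0.5)
        two = total_loss(0.2, 0.4, 0.6, 0.8, w, "DropoutCAE", contractive=1.0)
        assert two.total == pytest.approx(2 * one.total)

    def test_missing_regularizer_component_rejected(self):
        with pytest.raises(ValueError, match="contractive"):
            total_loss(0, 0, 0, 0, LossWeights(), "CAE")
        with pytest.raises(ValueError, match="kl"):
            total_loss(0, 0, 0, 0, LossWeights(), "VAE")


class TestBalancedAccuracy:
    def test_mean_per_class_recall_example(self):
        y = ["A", "A", "A", "B"]
        yh = ["A", "A", "B", "B"]
        assert balanced_accuracy(y, yh) == pytest.approx(5 / 6)

    def test_perfect_prediction(self):
        y = ["A", "B", "C"] * 4
        assert balanced_accuracy(y, y) == 1.0

    def test_majority_classifier_on_imbalanced_binary(self):
        y = np.array(["normal"] * 95 + ["tumor"] * 5)
        yh = np.full(100, "normal")
        assert (y == yh).mean() == pytest.approx(0.95)
        assert balanced_accuracy(y, yh) == pytest.approx(0.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_confusion_matrix_recall_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 6)
        n = rng.integers(k, 60)
        classes = np.arange(k)
        y = np.concatenate([classes, rng.integers(k, size=n - k)])  # every class present
        yh = rng.integers(k, size=n)
        recalls = [(yh[y == c] == c).mean() for c in classes]
        assert balanced_accuracy(y, yh) == pytest.approx(np.mean(recalls), rel=1e-12)
        assert balanced_accuracy(y, yh) == pytest.approx(
            balanced_accuracy_score(y, yh), rel=1e-12
        )

    def test_invariant_under_consistent_relabeling(self):
        rng = np.random.default_rng(5)
        y = rng.integers(3, size=50)
        yh = rng.integers(3, size=50)
        mapping = {0: 2, 1: 0, 2: 1}
        y2 = np.array([mapping[v] for v in y])
        yh2 = np.array([mapping[v] for v in yh])
        assert balanced_accuracy(y, yh) == pytest.approx(balanced_accuracy(y2, yh2))

    def test_sample_weights_follow_adjusted_weight_definition(self):
        y = np.array(["A", "A", "B"])
        yh = np.array(["A", "B", "B"])
        w = np.array([3.0, 1.0, 2.0])
        # w_hat = [3/4, 1/4, 1]; correct indicators [1, 0, 1]
        expected = (3 / 4 + 1.0) / (3 / 4 + 1 / 4 + 1.0)
        assert balanced_accuracy(y, yh, w) == pytest.approx(expected)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy([], [])


class TestClassificationReport:
    def test_two_class_counts_hand_computed(self):
        # confusion (predicted x true): [[3, 1], [0, 6]]
        y = ["a"] * 3 + ["b"] * 7
        yh = ["a", "a", "a", "a"] + ["b"] * 6
        rep = classification_report(y, yh, ["a", "b"])
        assert rep.confusion.tolist() == [[3, 1], [0, 6]]
        assert rep.sensitivity["a"] == pytest.approx(1.0)
        assert rep.sensitivity["b"] == pytest.approx(6 / 7)
        assert rep.specificity["a"] == pytest.approx(6 / 7)
        assert rep.specificity["b"] == pytest.approx(1.0)

    def test_diagonal_confusion_gives_perfect_rates(self):
        y = ["x", "y", "z"] * 3
        rep = classification_report(y, y, ["x", "y", "z"])
        assert np.all(np.diag(rep.confusion) == 3)
        assert all(v == 1.0 for v in rep.sensitivity.values())
        assert all(v == 1.0 for v in rep.specificity.values())

    def test_grand_total_is_sample_count(self):
        rng = np.random.default_rng(0)
        y = rng.choice(["a", "b", "c"], size=37)
        yh = rng.choice(["a", "b", "c"], size=37)
        rep = classification_report(y, yh, ["a", "b", "c"])
        assert rep.confusion.sum() == 37

    def test_unseen_label_rejected(self):
        with pytest.raises(ValueError, match="not in class"):
            classification_report(["a"], ["q"], ["a", "b"])


class TestSubtypeAccuracy:
    def _report(self, y, yh, vocab):
        return classification_report(y, yh, vocab)

    def test_all_correct_restriction_scores_one(self):
        vocab = ["A1", "A2", "B1"]
        y = ["A1", "A2", "B1"] * 5
        rep = self._report(y, y, vocab)
        _, acc = subtype_accuracy(rep, {"A": ("A1", "A2")})
        assert acc == 1.0

    def test_seventeen_errors_among_3120(self):
        # two subtypes of one tissue, 3120 samples total, 17 misclassified
        y = ["A1"] * 1560 + ["A2"] * 1560
        yh = ["A1"] * 1551 + ["A2"] * 9 + ["A1"] * 8 + ["A2"] * 1552
        rep = self._report(y, yh, ["A1", "A2"])
        _, acc = subtype_accuracy(rep, {"A": ("A1", "A2")})
        assert acc == pytest.approx(1 - 17 / 3120)
        assert round(acc * 100, 1) == 99.5 or round(acc * 100, 1) == 99.4

    def test_single_disease_tissue_excluded(self):
        vocab = ["A1", "A2", "B1"]
        y = ["A1", "A2", "B1"] * 4
        yh = ["A1", "A2", "A1"] * 4  # B1 always wrong but B is single-disease
        rep = self._report(y, yh, vocab)
        tables, acc = subtype_accuracy(rep, {"A": ("A1", "A2"), "B": ("B1",)})
        assert "B" not in tables
        assert acc == 1.0

    def test_unknown_disease_in_map_rejected(self):
        rep = self._report(["A1"], ["A1"], ["A1"])
        with pytest.raises(ValueError, match="unknown"):
            subtype_accuracy(rep, {"A": ("A1", "ZZ")})
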