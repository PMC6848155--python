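"""Robustness sweeps, comparisons, McNemar and embeddings."""

import numpy as np
import pytest
from scipy import stats
from sklearn.datasets import make_blobs
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from cicnet import (
    baseline_classifier_compare,
    default_dropout_grid,
    default_noise_grid,
    dimred_compare,
    embed_2d,
    mcnemar_test,
    random_and_majority_baselines,
    robustness_sweep,
)
from cicnet.evaluation import mcnemar_counts
from cicnet.training import evaluate


@pytest.fixture(scope="module")
def sweep(quick_model, tiny_dataset):
    grid = np.array([0.0, 0.1, 0.3, 0.5])
    return robustness_sweep(
        quick_model, tiny_dataset, kind="dropout_fraction", grid=grid, seed=0
    )


@pytest.fixture(scope="module")
def blobs():
    X, y = make_blobs(
        n_samples=200, centers=2, cluster_std=0.5, random_state=0, n_features=5
    )
    return X, np.array([f"class{v}" for v in y])


class TestRobustnessSweep:

    def test_zero_perturbation_matches_clean_evaluation_exactly(
        self, sweep, quick_model, tiny_dataset
    ):
        breakdown, tissue_rep, disease_rep = evaluate(quick_model, tiny_dataset)
        assert sweep.mrna_mse[0] == breakdown.mrna_mse
        assert sweep.mirna_mse[0] == breakdown.mirna_mse
        assert sweep.tissue_balanced_accuracy[0] == tissue_rep.balanced_accuracy
        assert sweep.disease_balanced_accuracy[0] == disease_rep.balanced_accuracy

    def test_default_grids_have_published_step_counts(self):
        dropout = default_dropout_grid()
        noise = default_noise_grid()
        assert len(dropout) == 51
        assert dropout[0] == 0.0 and dropout[-1] == 0.50
        assert len(noise) == 26
        assert noise[0] == 0.0 and noise[-1] == 0.25
        assert np.allclose(np.diff(dropout), 0.01)
        assert np.allclose(np.diff(noise), 0.01)

    def test_metrics_are_finite_across_the_grid(self, sweep):
        for arr in (sweep.mrna_mse, sweep.mirna_mse, sweep.tissue_accuracy):
            assert np.all(np.isfinite(arr))

    def test_untrained_model_rejected(self, tiny_dataset):
        from cicnet import ArchitectureConfig, build_model

        model = build_model(ArchitectureConfig(), 300, 40, 4, 8, seed=0)
        with pytest.raises(ValueError, match="trained"):
            robustness_sweep(model, tiny_dataset, kind="dropout_fraction")

    def test_nonincreasing_grid_rejected(self, quick_model, tiny_dataset):
        with pytest.raises(ValueError, match="increasing"):
            robustness_sweep(
                quick_model, tiny_dataset, "dropout_fraction", grid=[0.0, 0.2, 0.1]
            )

    def test_zeroed_fraction_tracks_grid_within_binomial_tolerance(self):
        from cicnet import ExpressionMatrix, inject_missing

        rng = np.random.default_rng(8)
        values = rng.random((200, 300)) + 0.01  # strictly positive
        m = ExpressionMatrix(
            values,
            [f"S{i}" for i in range(200)],
            [f"g{j}" for j in range(300)],
        )
        n = values.size
        for frac in (0.1, 0.3, 0.5):
            out = inject_missing(m, frac, seed=1)
            observed = (out.values == 0).mean()
            assert abs(observed - frac) < 4 * np.sqrt(frac * (1 - frac) / n) + 1e-3


class TestMcNemar:
    def test_continuity_corrected_chi2_closed_form(self):
        stat, p = mcnemar_counts(10, 2, method="chi2")
        assert stat == pytest.approx(49 / 12)
        assert p == pytest.approx(float(stats.chi2.sf(49 / 12, 1)))

    def test_identical_predictions_give_p_one(self):
        truth = np.array(["a", "b"] * 10)
        pred = np.array(["a", "a"] * 10)
        stat, p, b, c = mcnemar_test(pred, pred, truth)
        assert (b, c) == (0, 0)
        assert p == 1.0

    def test_exact_variant_agrees_with_binomial_tail_for_all_small_tables(self):
        for n in range(1, 21):
            for b in range(n + 1):
                c = n - b
                _, p = mcnemar_counts(b, c, method="exact")
                expected = float(stats.binomtest(min(b, c), n, 0.5).pvalue)
                assert p == pytest.approx(expected, rel=1e-12), (b, c)

    def test_agrees_with_statsmodels_oracle(self):
        # exact branch
        _, p_exact = mcnemar_counts(7, 3, method="exact")
        sm = sm_mcnemar(np.array([[0, 7], [3, 0]]), exact=True)
        assert p_exact == pytest.approx(float(sm.pvalue), rel=1e-10)
        # chi2 branch with continuity correction
        stat, p_chi2 = mcnemar_counts(40, 20, method="chi2")
        sm = sm_mcnemar(np.array([[0, 40], [20, 0]]), exact=False, correction=True)
        assert stat == pytest.approx(float(sm.statistic))
        assert p_chi2 == pytest.approx(float(sm.pvalue), rel=1e-10)

    def test_counts_from_prediction_vectors(self):
        truth = np.array(["x"] * 6)
        pred_a = np.array(["x", "x", "x", "x", "y", "y"])
        pred_b = np.array(["x", "y", "y", "x", "x", "y"])
        _, _, b, c = mcnemar_test(pred_a, pred_b, truth)
        assert (b, c) == (2, 1)


class TestEmbed2d:
    def test_pca_scores_are_centered(self):
        X = np.random.default_rng(0).normal(size=(30, 5)) + 3.0
        coords = embed_2d(X, method="pca", seed=0)
        assert coords.shape == (30, 2)
        assert np.allclose(coords.mean(axis=0), 0.0, atol=1e-9)

    def test_pca_on_2d_input_preserves_pairwise_distances(self):
        X = np.random.default_rng(1).normal(size=(20, 2))
        coords = embed_2d(X, method="pca", seed=0)
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(coords), pdist(X), atol=1e-9)

    def test_tsne_is_seed_deterministic(self):
        X = np.random.default_rng(2).normal(size=(40, 5))
        a = embed_2d(X, method="tsne", seed=3)
        b = embed_2d(X, method="tsne", seed=3)
        assert np.array_equal(a, b)

    def test_constant_matrix_rejected_for_tsne(self):
        with pytest.raises(ValueError, match="constant"):
            embed_2d(np.ones((10, 3)), method="tsne")


class TestReferenceBaselines:
    def test_majority_on_95_5_binary(self):
        labels = np.array(["normal"] * 95 + ["tumor"] * 5)
        res = random_and_majority_baselines(labels, mode="majority")
        assert res["conventional_accuracy"] == pytest.approx(0.95)
        assert res["balanced_accuracy"] == pytest.approx(0.5)

    def test_random_uniform_two_balanced_classes(self):
        rng = np.random.default_rng(0)
        labels = rng.permutation(np.array(["a", "b"] * 50000))
        res = random_and_majority_baselines(labels, mode="random_uniform", seed=1)
        assert res["conventional_accuracy"] == pytest.approx(0.5, abs=0.005)

    def test_random_uniform_33_balanced_classes(self):
        classes = [f"c{i}" for i in range(33)]
        labels = np.repeat(classes, 3031)  # ~1e5 samples
        res = random_and_majority_baselines(labels, mode="random_uniform", seed=2)
        assert res["conventional_accuracy"] == pytest.approx(1 / 33, abs=0.005)


class TestComparisons:

    def test_separable_blobs_score_near_perfect(self, blobs):
        X, y = blobs
        results = baseline_classifier_compare(
            X, y, algorithms=("knn", "sgd"), hpo_iters=4, seed=0
        )
        for r in results:
            assert r.balanced_accuracies.max() >= 0.99

    def test_permuted_labels_score_near_chance(self, blobs):
        X, y = blobs
        y_perm = np.random.default_rng(3).permutation(y)
        results = baseline_classifier_compare(
            X, y_perm, algorithms=("knn",), hpo_iters=3, seed=0
        )
        assert abs(results[0].balanced_accuracies.mean() - 0.5) < 0.12

    def test_same_seed_identical_accuracy_vectors(self, blobs):
        X, y = blobs
        a = baseline_classifier_compare(X, y, algorithms=("knn",), hpo_iters=3, seed=5)
        b = baseline_classifier_compare(X, y, algorithms=("knn",), hpo_iters=3, seed=5)
        assert np.array_equal(a[0].balanced_accuracies, b[0].balanced_accuracies)

    def test_unknown_algorithm_rejected(self, blobs):
        X, y = blobs
        with pytest.raises(ValueError, match="unknown"):
            baseline_classifier_compare(X, y, algorithms=("mystery",))

    def test_dimred_requires_matching_cic_dimension(self, blobs):
        X, y = blobs
        with pytest.raises(ValueError, match="must equal"):
            dimred_compare(X, X[:, :3], y, dim=2)

    def test_rank_limited_data_loses_nothing_under_pca(self):
        # rank-2 data in 10 dimensions: PCA-2 is lossless, so the ensemble
        # should match its own accuracy on the raw matrix within fold noise
        rng = np.random.default_rng(0)
        Z, y = make_blobs(n_samples=150, centers=3, cluster_std=1.0, random_state=1)
        X = Z @ rng.normal(size=(2, 10))
        labels = np.array([f"c{v}" for v in y])
        results = dimred_compare(
            X, Z, labels, dim=2, seed=0, methods=("pca",), cv_folds=3
        )
        by_rep = {r.representation: r.mean for r in results}
        assert abs(by_rep["pca2"] - by_rep["cic"]) < 0.05

    def test_shared_folds_across_representations(self, blobs):
        X, y = blobs
        results = dimred_compare(X, X[:, :2], y, dim=2, seed=0, methods=("pca",), cv_folds=3)
        for r in results:
            assert r.pooled_predictions is not None
            assert len(r.pooled_predictions) == len(y)
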