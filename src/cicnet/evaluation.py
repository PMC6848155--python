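"""Experiment harness: robustness sweeps, classifier and dimensionality
reduction comparisons, paired significance testing and 2-D embeddings.

All comparisons use balanced accuracy (conventional accuracy is reported
alongside) and identical fold assignments across representations, so a
paired McNemar test on the pooled out-of-fold predictions is valid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.calibration import CalibratedClassifierCV
from sklearn.decomposition import PCA, IncrementalPCA, KernelPCA, SparsePCA
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier, VotingClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.manifold import TSNE
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .data import PairedDataset
from .networks import ModelState, predict
from .objectives import balanced_accuracy, classification_report, mse
from .synthetic import inject_gaussian_noise, inject_missing
from . import hpo as _hpo

logger = logging.getLogger(__name__)

__all__ = [
    "RobustnessCurve",
    "ComparisonResult",
    "robustness_sweep",
    "default_dropout_grid",
    "default_noise_grid",
    "baseline_classifier_compare",
    "dimred_compare",
    "mcnemar_test",
    "embed_2d",
    "random_and_majority_baselines",
]


# ---------------------------------------------------------------------------
# robustness


@dataclass
class RobustnessCurve:
    """Metrics of a trained model under increasing input perturbation."""

    kind: str  # dropout_fraction | gaussian_sd
    grid: np.ndarray
    mrna_mse: np.ndarray
    mirna_mse: np.ndarray
    tissue_accuracy: np.ndarray
    disease_accuracy: np.ndarray
    tissue_balanced_accuracy: np.ndarray
    disease_balanced_accuracy: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "perturbation": self.grid,
                "mrna_mse": self.mrna_mse,
                "mirna_mse": self.mirna_mse,
                "tissue_accuracy": self.tissue_accuracy,
                "disease_accuracy": self.disease_accuracy,
                "tissue_balanced_accuracy": self.tissue_balanced_accuracy,
                "disease_balanced_accuracy": self.disease_balanced_accuracy,
            }
        )


def default_dropout_grid() -> np.ndarray:
    """Missing-value sweep: 0 to 50% in 1% steps (51 points)."""
    return np.round(np.arange(0.0, 0.51, 0.01), 2)


def default_noise_grid() -> np.ndarray:
    """Additive-noise sweep: SD 0 to 0.25 in 0.01 steps (26 points)."""
    return np.round(np.arange(0.0, 0.26, 0.01), 2)


def robustness_sweep(
    model: ModelState,
    test: PairedDataset,
    kind: str,
    grid: np.ndarray | None = None,
    seed: int = 0,
) -> RobustnessCurve:
    """Evaluate a trained model on increasingly perturbed test inputs.

    ``kind="dropout_fraction"`` zeroes a random fraction of input entries;
    ``kind="gaussian_sd"`` adds zero-mean Gaussian noise of the given SD.
    Regression errors are always measured against the clean targets.  At
    perturbation 0 the inputs are bit-identical to the clean evaluation.
    """
    if not model.trained:
        raise ValueError("robustness_sweep requires a trained model")
    if kind not in ("dropout_fraction", "gaussian_sd"):
        raise ValueError(f"unknown perturbation kind {kind!r}")
    if grid is None:
        grid = default_dropout_grid() if kind == "dropout_fraction" else default_noise_grid()
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if kind == "dropout_fraction" and (grid.min() < 0 or grid.max() > 1):
        raise ValueError("dropout grid must lie in [0, 1]")
    if kind == "gaussian_sd" and grid.min() < 0:
        raise ValueError("noise grid must be nonnegative")

    rng = np.random.default_rng(seed)
    tissues, diseases = test.tissues(), test.diseases()
    cols = {k: [] for k in ("mrna_mse", "mirna_mse", "ta", "da", "tba", "dba")}
    for level in grid:
        if level == 0:
            perturbed = test.mrna
        elif kind == "dropout_fraction":
            perturbed = inject_missing(test.mrna, float(level), seed=int(rng.integers(2**31)))
        else:
            perturbed = inject_gaussian_noise(
                test.mrna, float(level), seed=int(rng.integers(2**31))
            )
        out = predict(model, perturbed.values)
        t_pred = np.array([model.tissue_vocab[i] for i in out.tissue_hat.argmax(1)])
        d_pred = np.array([model.disease_vocab[i] for i in out.disease_hat.argmax(1)])
        cols["mrna_mse"].append(mse(test.mrna.values, out.mrna_hat))
        cols["mirna_mse"].append(mse(test.mirna.values, out.mirna_hat))
        cols["ta"].append(float((t_pred == tissues).mean()))
        cols["da"].append(float((d_pred == diseases).mean()))
        cols["tba"].append(balanced_accuracy(tissues, t_pred))
        cols["dba"].append(balanced_accuracy(diseases, d_pred))
    return RobustnessCurve(
        kind=kind,
        grid=grid,
        mrna_mse=np.array(cols["mrna_mse"]),
        mirna_mse=np.array(cols["mirna_mse"]),
        tissue_accuracy=np.array(cols["ta"]),
        disease_accuracy=np.array(cols["da"]),
        tissue_balanced_accuracy=np.array(cols["tba"]),
        disease_balanced_accuracy=np.array(cols["dba"]),
    )


# ---------------------------------------------------------------------------
# classifier comparisons


@dataclass
class ComparisonResult:
    """Accuracy of one method on one representation for one task."""

    method: str
    representation: str
    task: str
    balanced_accuracies: np.ndarray  # across HPO iterations or CV folds
    conventional_accuracies: np.ndarray
    pooled_predictions: np.ndarray | None = None  # out-of-fold, for pairing
    best_hyperparameters: dict | None = None

    @property
    def mean(self) -> float:
        return float(self.balanced_accuracies.mean())

    @property
    def sd(self) -> float:
        return float(self.balanced_accuracies.std(ddof=1)) if len(
            self.balanced_accuracies
        ) > 1 else 0.0


_BASELINE_FACTORY = {
    "knn": lambda h, seed: KNeighborsClassifier(
        n_neighbors=h.get("n_neighbors", 5), weights=h.get("weights", "uniform")
    ),
    "extra_trees": lambda h, seed: ExtraTreesClassifier(
        n_estimators=h.get("n_estimators", 100),
        max_depth=h.get("max_depth"),
        random_state=seed,
    ),
    "random_forest": lambda h, seed: RandomForestClassifier(
        n_estimators=h.get("n_estimators", 100),
        max_depth=h.get("max_depth"),
        random_state=seed,
    ),
    "sgd": lambda h, seed: SGDClassifier(
        loss=h.get("loss", "hinge"), alpha=h.get("alpha", 1e-4), random_state=seed
    ),
    "svm": lambda h, seed: SVC(
        C=h.get("C", 1.0), kernel=h.get("kernel", "rbf"), random_state=seed
    ),
}

_BASELINE_SPACES = {
    "knn": {"n_neighbors": (1, 3, 5, 11, 21), "weights": ("uniform", "distance")},
    "extra_trees": {"n_estimators": (50, 100, 200), "max_depth": (None, 5, 10, 20)},
    "random_forest": {"n_estimators": (50, 100, 200), "max_depth": (None, 5, 10, 20)},
    "sgd": {
        "loss": ("hinge", "log_loss", "modified_huber"),
        "alpha": (1e-5, 1e-4, 1e-3, 1e-2),
    },
    "svm": {"C": (0.1, 1.0, 10.0, 100.0), "kernel": ("rbf", "linear", "poly")},
}


def _cv_balanced_accuracy(
    clf_factory, h: dict, X, y, k: int, seed: int
) -> tuple[float, float, np.ndarray]:
    """Stratified k-fold CV; returns (balanced, conventional, pooled preds)."""
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=object)
    for train_idx, test_idx in skf.split(X, y):
        clf = clf_factory(h, seed)
        clf.fit(X[train_idx], y[train_idx])
        pred[test_idx] = clf.predict(X[test_idx])
    pred = pred.astype(str)
    return balanced_accuracy(y, pred), float((pred == y).mean()), pred


def baseline_classifier_compare(
    X: np.ndarray,
    labels: np.ndarray,
    algorithms=("knn", "extra_trees", "random_forest", "sgd", "svm"),
    hpo_iters: int = 100,
    cv_folds: int = 5,
    task: str = "disease",
    representation: str = "raw_mrna",
    seed: int = 0,
) -> list[ComparisonResult]:
    """Tune each classical classifier with the TPE optimizer and score it
    by stratified k-fold CV balanced accuracy.

    The per-iteration accuracy distribution is retained (one entry per
    HPO trial), mirroring violin-style comparisons across tuning runs.
    """
    X = np.asarray(X)
    labels = np.asarray(labels)
    if len(X) != len(labels):
        raise ValueError("representation rows must match label count")
    results = []
    for i, algo in enumerate(algorithms):
        if algo not in _BASELINE_FACTORY:
            raise ValueError(f"unknown algorithm {algo!r}")
        space = _hpo.SearchSpace(_BASELINE_SPACES[algo])
        records: dict[tuple, tuple[float, float, np.ndarray]] = {}

        def objective(h, _algo=algo, _records=records):
            key = tuple(sorted((k, repr(v)) for k, v in h.items()))
            if key not in _records:
                _records[key] = _cv_balanced_accuracy(
                    _BASELINE_FACTORY[_algo], h, X, labels, cv_folds, seed
                )
            return 1.0 - _records[key][0]  # minimize 1 - balanced accuracy

        n_iter = min(hpo_iters, space.size)
        best, history = _hpo.bayesian_optimize(
            objective, space, n_iter=n_iter, seed=seed + i
        )
        bals = np.array([1.0 - t.score for t in history])
        convs = np.array(
            [records[_hpo._key(t.hyperparameters)][1] for t in history]
        )
        best_pred = records[_hpo._key(best.hyperparameters)][2]
        results.append(
            ComparisonResult(
                method=algo,
                representation=representation,
                task=task,
                balanced_accuracies=bals,
                conventional_accuracies=convs,
                pooled_predictions=best_pred,
                best_hyperparameters=best.hyperparameters,
            )
        )
        logger.info("%s: best balanced accuracy %.3f", algo, bals.max())
    return results


def _ensemble(seed: int):
    """Soft-voting ensemble of a calibrated SVM and a random forest, used
    for the dimensionality reduction comparison."""
    svm = CalibratedClassifierCV(SVC(random_state=seed), ensemble=False)
    return VotingClassifier(
        estimators=[
            ("svm", svm),
            ("rf", RandomForestClassifier(n_estimators=100, random_state=seed)),
        ],
        voting="soft",
    )


def dimred_compare(
    mrna_values: np.ndarray,
    cics: np.ndarray,
    labels: np.ndarray,
    dim: int = 8,
    cv_folds: int = 5,
    task: str = "disease",
    seed: int = 0,
    methods=("pca", "kernel_pca", "sparse_pca", "incremental_pca"),
) -> list[ComparisonResult]:
    """Compare CICs against classical reductions of the raw mRNA matrix.

    Each reduction maps the mRNA matrix to ``dim`` components; every
    representation (including the CICs) is fed to the same soft-voting
    SVM + random-forest ensemble under identical fold assignments, so
    the resulting pooled predictions are pairwise comparable.
    """
    mrna_values = np.asarray(mrna_values)
    cics = np.asarray(cics)
    labels = np.asarray(labels)
    if dim > mrna_values.shape[1]:
        raise ValueError("dim exceeds the mRNA feature count")
    if cics.shape[1] != dim:
        raise ValueError(f"CIC dimension {cics.shape[1]} must equal dim {dim}")

    reducers = {
        "pca": PCA(n_components=dim, random_state=seed),
        "kernel_pca": KernelPCA(n_components=dim, kernel="rbf", random_state=seed),
        "sparse_pca": SparsePCA(n_components=dim, random_state=seed, max_iter=200),
        "incremental_pca": IncrementalPCA(n_components=dim),
    }
    representations: dict[str, np.ndarray] = {"cic": cics}
    for name in methods:
        if name not in reducers:
            raise ValueError(f"unknown reduction method {name!r}")
        representations[f"{name}{dim}"] = reducers[name].fit_transform(mrna_values)

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    fold_pairs = list(skf.split(mrna_values, labels))  # shared across representations
    results = []
    for name, X in representations.items():
        bals, convs = [], []
        pred = np.empty(len(labels), dtype=object)
        for train_idx, test_idx in fold_pairs:
            clf = _ensemble(seed)
            clf.fit(X[train_idx], labels[train_idx])
            p = clf.predict(X[test_idx])
            pred[test_idx] = p
            bals.append(balanced_accuracy(labels[test_idx], p))
            convs.append(float((p == labels[test_idx]).mean()))
        results.append(
            ComparisonResult(
                method="svm_rf_ensemble",
                representation=name,
                task=task,
                balanced_accuracies=np.array(bals),
                conventional_accuracies=np.array(convs),
                pooled_predictions=pred.astype(str),
            )
        )
        logger.info("%s: mean balanced accuracy %.3f", name, np.mean(bals))
    return results


# ---------------------------------------------------------------------------
# significance and baselines


def mcnemar_counts(b: int, c: int, method: str = "auto") -> tuple[float, float]:
    """McNemar statistic and p-value from discordant counts.

    ``chi2`` uses the continuity-corrected statistic (|b-c|-1)^2/(b+c)
    with 1 df; ``exact`` uses the two-sided binomial tail of min(b, c)
    out of b + c at p = 1/2; ``auto`` picks exact when b + c < 25.
    """
    if b + c == 0:
        return 0.0, 1.0  # no discordance
    if method == "auto":
        method = "exact" if b + c < 25 else "chi2"
    if method == "exact":
        p = float(stats.binomtest(min(b, c), n=b + c, p=0.5).pvalue)
        return float(min(b, c)), min(p, 1.0)
    if method == "chi2":
        stat = (abs(b - c) - 1) ** 2 / (b + c)
        return float(stat), float(stats.chi2.sf(stat, df=1))
    raise ValueError(f"unknown method {method!r}")


def mcnemar_test(pred_a, pred_b, truth, method: str = "auto") -> tuple[float, float, int, int]:
    """Paired comparison of two classifiers on the same samples.

    b counts samples classifier A gets right and B wrong; c the reverse.
    Returns (statistic, p_value, b, c); see :func:`mcnemar_counts` for
    the statistic choice.
    """
    pred_a, pred_b, truth = map(np.asarray, (pred_a, pred_b, truth))
    if not (len(pred_a) == len(pred_b) == len(truth)):
        raise ValueError("prediction and truth vectors must have equal length")
    a_right = pred_a == truth
    b_right = pred_b == truth
    b = int(np.sum(a_right & ~b_right))
    c = int(np.sum(~a_right & b_right))
    stat, p = mcnemar_counts(b, c, method=method)
    return stat, p, b, c


def embed_2d(X: np.ndarray, method: str = "pca", seed: int = 0, perplexity: float = 30.0):
    """Project samples to 2-D for visualization (PCA scores or t-SNE)."""
    X = np.asarray(X, dtype=float)
    if len(X) < 3:
        raise ValueError("need at least 3 samples to embed")
    if method == "pca":
        if np.allclose(X.var(axis=0), 0):
            logger.warning("embedding a zero-variance matrix: PCA scores are zero")
        return PCA(n_components=2, random_state=seed).fit_transform(X)
    if method == "tsne":
        if np.allclose(X.var(axis=0), 0):
            raise ValueError("t-SNE is undefined for a constant matrix")
        perplexity = min(perplexity, (len(X) - 1) / 3)
        return TSNE(
            n_components=2, random_state=seed, perplexity=perplexity, init="pca"
        ).fit_transform(X)
    raise ValueError(f"unknown embedding method {method!r}")


def random_and_majority_baselines(
    labels, n_classes: int | None = None, mode: str = "random_uniform", seed: int = 0
) -> dict[str, float]:
    """Reference accuracies of label-blind classifiers.

    ``random_uniform`` assigns each sample a uniformly random class;
    ``majority`` always predicts the modal class.  Returns conventional
    and balanced accuracy.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be nonempty")
    classes = np.unique(labels)
    if n_classes is None:
        n_classes = len(classes)
    if mode == "random_uniform":
        rng = np.random.default_rng(seed)
        pred = classes[rng.integers(len(classes), size=len(labels))]
    elif mode == "majority":
        values, counts = np.unique(labels, return_counts=True)
        pred = np.full(len(labels), values[counts.argmax()])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {
        "conventional_accuracy": float((pred == labels).mean()),
        "balanced_accuracy": balanced_accuracy(labels, pred),
    }
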