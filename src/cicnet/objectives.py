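"""Losses, regularizers and evaluation metrics for the multi-task objective.

The total training objective is a weighted sum of four task losses —
mean squared error for the two expression regressions, one-minus-cosine
for the two classifications — plus an architecture-dependent regularizer:
the squared Frobenius norm of the encoder Jacobian for contractive kinds,
or the KL divergence to a standard-normal prior for variational kinds.
Default task weights are 0.5 for each classification and 1e-3 for each
regression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _autodiff as ad
from ._autodiff import Tensor
from .networks import ModelState, encoder_graph, jacobian_frobenius_sq

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "MetricReport",
    "mse",
    "cosine_classification_loss",
    "contractive_penalty",
    "kl_gaussian",
    "total_loss",
    "balanced_accuracy",
    "classification_report",
    "subtype_accuracy",
]


@dataclass(frozen=True)
class LossWeights:
    """Task weights of the multi-task objective (all nonnegative)."""

    w_tissue: float = 0.5
    w_disease: float = 0.5
    w_mrna: float = 1e-3
    w_mirna: float = 1e-3
    lambda_contractive: float = 1e-4
    kl_weight: float = 1.0

    def __post_init__(self):
        if min(
            self.w_tissue,
            self.w_disease,
            self.w_mrna,
            self.w_mirna,
            self.lambda_contractive,
            self.kl_weight,
        ) < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass(frozen=True)
class LossBreakdown:
    """Per-task loss values and their weighted total."""

    mrna_mse: float
    mirna_mse: float
    tissue_cos: float
    disease_cos: float
    contractive: float = 0.0
    kl: float = 0.0
    total: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def _to_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else ad.constant(np.asarray(x, dtype=float))


def mse(target, prediction) -> Tensor | float:
    """Mean over all entries of the squared difference."""
    t, p = _to_tensor(target), _to_tensor(prediction)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {p.shape}")
    out = ((t - p) ** 2).mean()
    return out if isinstance(target, Tensor) or isinstance(prediction, Tensor) else float(out.data)


def mae(target, prediction) -> float:
    target, prediction = np.asarray(target), np.asarray(prediction)
    if target.shape != prediction.shape:
        raise ValueError(f"shape mismatch: {target.shape} vs {prediction.shape}")
    return float(np.abs(target - prediction).mean())


def cosine_classification_loss(onehot, predicted) -> Tensor | float:
    """Mean over samples of 1 - cos(target row, predicted row); in [0, 2].

    With nonnegative row-stochastic inputs the loss lies in [0, 1]: 0 for
    a perfect prediction, 1 - 1/sqrt(K) for a uniform prediction over K
    classes, and 1 when all probability mass is on wrong classes.
    """
    t, p = _to_tensor(onehot), _to_tensor(predicted)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {p.shape}")
    t_norm = ad.sqrt((t**2).sum(axis=1))
    p_norm = ad.sqrt((p**2).sum(axis=1))
    if np.any(t_norm.data == 0) or np.any(p_norm.data == 0):
        raise ValueError("cosine loss undefined for zero-norm rows")
    cos = (t * p).sum(axis=1) / (t_norm * p_norm)
    out = (1.0 - cos).mean()
    return out if isinstance(onehot, Tensor) or isinstance(predicted, Tensor) else float(out.data)


def contractive_penalty(model: ModelState, X: np.ndarray) -> float:
    """Mean over the batch of the squared Frobenius norm of the encoder
    Jacobian d cic / d input, with the encoder in deterministic mode."""
    if model.config.is_variational:
        raise ValueError("contractive penalty is defined for CAE kinds only")
    _, _, _, cache = encoder_graph(model, X, training=False)
    return float(jacobian_frobenius_sq(cache).data)


def kl_gaussian(mu_z, logvar_z) -> Tensor | float:
    """KL(N(mu, exp(logvar)) || N(0, I)), averaged over the batch."""
    mu, logvar = _to_tensor(mu_z), _to_tensor(logvar_z)
    if mu.shape != logvar.shape:
        raise ValueError(f"shape mismatch: {mu.shape} vs {logvar.shape}")
    if not (np.isfinite(mu.data).all() and np.isfinite(logvar.data).all()):
        raise ValueError("kl_gaussian received non-finite inputs")
    per_sample = 0.5 * (ad.exp(logvar) + mu**2 - 1.0 - logvar).sum(axis=-1)
    out = per_sample.mean()
    graph = isinstance(mu_z, Tensor) or isinstance(logvar_z, Tensor)
    return out if graph else float(out.data)


def total_loss(
    mrna_mse,
    mirna_mse,
    tissue_cos,
    disease_cos,
    weights: LossWeights,
    kind: str = "CAE",
    contractive=None,
    kl=None,
):
    """Assemble the weighted multi-task objective for one architecture kind.

    Contractive kinds require the Jacobian penalty, variational kinds the
    KL term.  When called with plain floats returns a LossBreakdown; with
    graph tensors returns (total Tensor, LossBreakdown of the values).
    """
    from .networks import KINDS

    if kind not in KINDS:
        raise ValueError(f"unknown architecture kind {kind!r}")
    variational = kind in ("VAE", "DropoutVAE")
    if variational:
        if kl is None:
            raise ValueError("VAE kinds require the kl component")
        contractive = None
    else:
        if contractive is None:
            raise ValueError("CAE kinds require the contractive component")
        kl = None

    total = (
        weights.w_tissue * tissue_cos
        + weights.w_disease * disease_cos
        + weights.w_mrna * mrna_mse
        + weights.w_mirna * mirna_mse
    )
    if variational:
        total = total + weights.kl_weight * kl
    else:
        total = total + weights.lambda_contractive * contractive

    def val(x):
        return float(x.data) if isinstance(x, Tensor) else float(x)

    breakdown = LossBreakdown(
        mrna_mse=val(mrna_mse),
        mirna_mse=val(mirna_mse),
        tissue_cos=val(tissue_cos),
        disease_cos=val(disease_cos),
        contractive=0.0 if contractive is None else val(contractive),
        kl=0.0 if kl is None else val(kl),
        total=val(total),
    )
    if isinstance(total, Tensor):
        return total, breakdown
    return breakdown


# ---------------------------------------------------------------------------
# metrics


def balanced_accuracy(y, y_hat, w=None) -> float:
    """Weighted balanced accuracy.

    Sample weights are adjusted by the total weight of the sample's true
    class, w_hat_i = w_i / sum_j 1(y_j = y_i) w_j, and the score is the
    adjusted-weight mean of the correctness indicator.  With uniform
    weights this equals the unweighted mean of per-class recalls.
    """
    y = np.asarray(y)
    y_hat = np.asarray(y_hat)
    if y.size == 0:
        raise ValueError("balanced_accuracy requires at least one sample")
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    w = np.ones(len(y), dtype=float) if w is None else np.asarray(w, dtype=float)
    class_weight = {c: w[y == c].sum() for c in np.unique(y)}
    w_hat = np.array([wi / class_weight[yi] for wi, yi in zip(w, y)])
    return float(((y == y_hat) * w_hat).sum() / w_hat.sum())


@dataclass(frozen=True)
class MetricReport:
    """Classification metrics around a labeled confusion matrix.

    The confusion matrix is oriented with true classes as columns and
    predicted classes as rows.
    """

    class_vocab: tuple[str, ...]
    confusion: np.ndarray  # predicted x true counts
    balanced_accuracy: float
    conventional_accuracy: float
    sensitivity: dict[str, float]  # per-class recall
    specificity: dict[str, float]  # per-class one-vs-rest true-negative rate
    mse: float | None = None
    mae: float | None = None

    def to_json(self) -> str:
        d = {
            "class_vocab": list(self.class_vocab),
            "confusion": self.confusion.tolist(),
            "balanced_accuracy": self.balanced_accuracy,
            "conventional_accuracy": self.conventional_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mse": self.mse,
            "mae": self.mae,
        }
        return json.dumps(d, indent=2)

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.confusion,
            index=pd.Index(self.class_vocab, name="predicted"),
            columns=pd.Index(self.class_vocab, name="true"),
        )


def classification_report(y, y_hat, class_vocab, w=None) -> MetricReport:
    """Confusion matrix plus accuracies, per-class sensitivity/specificity."""
    y, y_hat = np.asarray(y), np.asarray(y_hat)
    vocab = tuple(class_vocab)
    pos = {c: i for i, c in enumerate(vocab)}
    for lab in np.unique(np.concatenate([y, y_hat])):
        if lab not in pos:
            raise ValueError(f"label {lab!r} not in class vocabulary")
    conf = np.zeros((len(vocab), len(vocab)), dtype=int)
    for t, p in zip(y, y_hat):
        conf[pos[p], pos[t]] += 1  # rows predicted, columns true
    n = conf.sum()
    sensitivity, specificity = {}, {}
    for c, i in pos.items():
        tp = conf[i, i]
        fn = conf[:, i].sum() - tp
        fp = conf[i, :].sum() - tp
        tn = n - tp - fn - fp
        sensitivity[c] = float(tp / (tp + fn)) if (tp + fn) else float("nan")
        specificity[c] = float(tn / (tn + fp)) if (tn + fp) else float("nan")
    return MetricReport(
        class_vocab=vocab,
        confusion=conf,
        balanced_accuracy=balanced_accuracy(y, y_hat, w),
        conventional_accuracy=float((y == y_hat).mean()),
        sensitivity=sensitivity,
        specificity=specificity,
    )


def subtype_accuracy(
    report: MetricReport, tissue_to_diseases: dict[str, tuple[str, ...]]
) -> tuple[dict[str, pd.DataFrame], float]:
    """Cancer-subtype discrimination within tissues that host >= 2 diseases.

    Restricts the disease confusion matrix to samples whose true disease
    belongs to a multi-disease tissue, keeping only confusions among that
    tissue's own diseases; accuracy is 1 - misclassified/total over the
    restriction.  Tissues with a single disease are excluded.
    """
    vocab = set(report.class_vocab)
    for tissue, diseases in tissue_to_diseases.items():
        unknown = set(diseases) - vocab
        if unknown:
            raise ValueError(f"tissue {tissue!r} lists unknown diseases {sorted(unknown)}")
    frame = report.confusion_frame()
    per_tissue: dict[str, pd.DataFrame] = {}
    correct = total = 0
    for tissue, diseases in tissue_to_diseases.items():
        diseases = [d for d in diseases if d != "Normal"]
        if len(diseases) < 2:
            continue
        sub = frame.loc[list(diseases), list(diseases)]
        per_tissue[tissue] = sub
        correct += int(np.diag(sub.to_numpy()).sum())
        total += int(sub.to_numpy().sum())
    if total == 0:
        raise ValueError("no tissue has two or more disease classes")
    return per_tissue, correct / total
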