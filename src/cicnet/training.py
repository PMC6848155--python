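"""Multi-task training loop, CIC extraction and k-fold cross-validation.

Training minimizes the weighted multi-task objective by mini-batch Adam.
Corruption layers (input noise, dropout, VAE sampling) are active only in
training mode; per-epoch metrics are always computed with them disabled.
Everything is seeded, so a (seed, config, dataset) triple reproduces the
fold assignment and the training trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _autodiff as ad
from .data import PairedDataset, encode_labels
from .networks import (
    ArchitectureConfig,
    ModelState,
    build_model,
    decoder_graph,
    encoder_graph,
    jacobian_frobenius_sq,
    predict,
)
from .objectives import (
    LossBreakdown,
    LossWeights,
    MetricReport,
    classification_report,
    cosine_classification_loss,
    kl_gaussian,
    mae,
    mse,
    total_loss,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "History",
    "EpochRecord",
    "fit",
    "evaluate",
    "extract_cics",
    "cross_validate",
    "CrossValidationResult",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings: fixed-epoch Adam, no early stopping."""

    epochs: int = 200
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: LossBreakdown
    test_loss: LossBreakdown | None
    train_tissue_acc: float
    train_disease_acc: float
    test_tissue_acc: float | None
    test_disease_acc: float | None


@dataclass
class History:
    """Per-epoch loss breakdowns and accuracies for train and test."""

    records: list[EpochRecord] = field(default_factory=list)

    def __len__(self):
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"epoch": r.epoch}
            row.update({f"train_{k}": v for k, v in r.train_loss.as_dict().items()})
            row["train_tissue_acc"] = r.train_tissue_acc
            row["train_disease_acc"] = r.train_disease_acc
            if r.test_loss is not None:
                row.update({f"test_{k}": v for k, v in r.test_loss.as_dict().items()})
                row["test_tissue_acc"] = r.test_tissue_acc
                row["test_disease_acc"] = r.test_disease_acc
            rows.append(row)
        return pd.DataFrame(rows)


class _Adam:
    def __init__(self, params: dict, cfg: TrainingConfig):
        self.params = params
        self.cfg = cfg
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        c = self.cfg
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * p.grad
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * p.grad**2
            mhat = self.m[k] / (1 - c.beta1**self.t)
            vhat = self.v[k] / (1 - c.beta2**self.t)
            p.data -= c.learning_rate * mhat / (np.sqrt(vhat) + c.adam_eps)


def _targets(dataset: PairedDataset):
    return (
        dataset.mrna.values,
        dataset.mirna.values,
        encode_labels(dataset.tissues(), dataset.tissue_vocab),
        encode_labels(dataset.diseases(), dataset.disease_vocab),
    )


def _batch_objective(model: ModelState, Xb, Yb, weights: LossWeights, rng):
    """Build the training-mode graph for one mini-batch; returns (total, breakdown)."""
    cfg = model.config
    z, mu, logvar, cache = encoder_graph(model, Xb, training=True, rng=rng)
    mrna_hat, mirna_hat, tissue_hat, disease_hat = decoder_graph(model, z, training=True)
    mrna_t, mirna_t, tissue_t, disease_t = Yb
    components = dict(
        mrna_mse=mse(ad.constant(mrna_t), mrna_hat),
        mirna_mse=mse(ad.constant(mirna_t), mirna_hat),
        tissue_cos=cosine_classification_loss(ad.constant(tissue_t), tissue_hat),
        disease_cos=cosine_classification_loss(ad.constant(disease_t), disease_hat),
    )
    if cfg.is_variational:
        components["kl"] = kl_gaussian(mu, logvar)
    else:
        components["contractive"] = jacobian_frobenius_sq(cache)
    return total_loss(weights=weights, kind=cfg.kind, **components)


def evaluate(
    model: ModelState, dataset: PairedDataset, weights: LossWeights | None = None
) -> tuple[LossBreakdown, MetricReport, MetricReport]:
    """Deterministic evaluation: loss breakdown plus tissue/disease reports."""
    weights = weights or LossWeights()
    mrna_t, mirna_t, tissue_t, disease_t = _targets(dataset)
    out = predict(model, dataset.mrna.values)
    components = dict(
        mrna_mse=mse(mrna_t, out.mrna_hat),
        mirna_mse=mse(mirna_t, out.mirna_hat),
        tissue_cos=cosine_classification_loss(tissue_t, out.tissue_hat),
        disease_cos=cosine_classification_loss(disease_t, out.disease_hat),
    )
    if model.config.is_variational:
        components["kl"] = kl_gaussian(out.mu_z, out.logvar_z)
    else:
        _, _, _, cache = encoder_graph(model, dataset.mrna.values, training=False)
        components["contractive"] = float(jacobian_frobenius_sq(cache).data)
    breakdown = total_loss(weights=weights, kind=model.config.kind, **components)
    tissue_pred = np.array(
        [model.tissue_vocab[i] for i in out.tissue_hat.argmax(axis=1)]
    )
    disease_pred = np.array(
        [model.disease_vocab[i] for i in out.disease_hat.argmax(axis=1)]
    )
    tissue_report = classification_report(dataset.tissues(), tissue_pred, model.tissue_vocab)
    disease_report = classification_report(dataset.diseases(), disease_pred, model.disease_vocab)
    object.__setattr__(tissue_report, "mse", components["mrna_mse"])
    object.__setattr__(tissue_report, "mae", mae(mrna_t, out.mrna_hat))
    object.__setattr__(disease_report, "mse", components["mirna_mse"])
    object.__setattr__(disease_report, "mae", mae(mirna_t, out.mirna_hat))
    return breakdown, tissue_report, disease_report


def fit(
    model: ModelState,
    train: PairedDataset,
    test: PairedDataset | None = None,
    config: TrainingConfig | None = None,
    record_history: bool = True,
) -> tuple[ModelState, History]:
    """Train all parts of the network simultaneously by mini-batch Adam."""
    config = config or TrainingConfig()
    batch = model.config.batch_size
    if train.n_samples % batch:
        raise ValueError(
            f"training set size {train.n_samples} is not a multiple of batch size "
            f"{batch}; use data.split_and_trim"
        )
    rng = np.random.default_rng(config.seed)
    optimizer = _Adam(model.params, config)
    X = train.mrna.values
    Y = _targets(train)
    history = History()
    n = train.n_samples
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            Xb = X[idx]
            Yb = tuple(t[idx] for t in Y)
            model.zero_grad()
            total, _ = _batch_objective(model, Xb, Yb, config.weights, rng)
            total.backward()
            optimizer.step()
        if record_history:
            tr_loss, tr_tis, tr_dis = evaluate(model, train, config.weights)
            if test is not None and test.n_samples:
                te_loss, te_tis, te_dis = evaluate(model, test, config.weights)
                rec = EpochRecord(
                    epoch,
                    tr_loss,
                    te_loss,
                    tr_tis.balanced_accuracy,
                    tr_dis.balanced_accuracy,
                    te_tis.balanced_accuracy,
                    te_dis.balanced_accuracy,
                )
            else:
                rec = EpochRecord(
                    epoch,
                    tr_loss,
                    None,
                    tr_tis.balanced_accuracy,
                    tr_dis.balanced_accuracy,
                    None,
                    None,
                )
            history.records.append(rec)
    model.trained = True
    return model, history


def extract_cics(model: ModelState, dataset: PairedDataset) -> pd.DataFrame:
    """Deterministic CICs for every sample, indexed by sample ID."""
    from .networks import encode

    codes = encode(model, dataset.mrna.values, stochastic=False)
    return pd.DataFrame(
        codes,
        index=pd.Index(dataset.sample_ids, name="sample_id"),
        columns=[f"cic_{j}" for j in range(codes.shape[1])],
    )


@dataclass
class CrossValidationResult:
    fold_assignment: pd.Series  # sample_id -> fold
    tissue_reports: list[MetricReport]
    disease_reports: list[MetricReport]
    pooled_tissue_report: MetricReport
    pooled_disease_report: MetricReport
    oof_cics: pd.DataFrame  # out-of-fold CIC per sample
    pooled_predictions: pd.DataFrame  # sample_id, true/pred tissue & disease

    def summary(self) -> pd.DataFrame:
        rows = []
        for task, reports, pooled in (
            ("tissue", self.tissue_reports, self.pooled_tissue_report),
            ("disease", self.disease_reports, self.pooled_disease_report),
        ):
            accs = np.array([r.balanced_accuracy for r in reports])
            rows.append(
                {
                    "task": task,
                    "mean_balanced_accuracy": accs.mean(),
                    "se_balanced_accuracy": accs.std(ddof=1) / np.sqrt(len(accs)),
                    "pooled_balanced_accuracy": pooled.balanced_accuracy,
                    "pooled_conventional_accuracy": pooled.conventional_accuracy,
                }
            )
        return pd.DataFrame(rows)


def _fold_assignment(labels: np.ndarray, k: int, rng, stratified: bool) -> np.ndarray:
    n = len(labels)
    folds = np.empty(n, dtype=int)
    if not stratified:
        perm = rng.permutation(n)
        for f, chunk in enumerate(np.array_split(perm, k)):
            folds[chunk] = f
        return folds
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        if len(idx) < k:
            logger.warning("class %r has fewer samples (%d) than folds (%d)", cls, len(idx), k)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def cross_validate(
    arch: ArchitectureConfig,
    dataset: PairedDataset,
    k: int = 5,
    config: TrainingConfig | None = None,
    seed: int = 0,
    stratified: bool = True,
) -> CrossValidationResult:
    """k-fold cross-validation of one architecture.

    Each sample is used exactly once as a test sample; out-of-fold CICs
    and predictions are pooled over folds.  The training partition of
    each fold is trimmed (never the test partition) so its size is a
    multiple of the batch size.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    config = config or TrainingConfig()
    rng = np.random.default_rng(seed)
    diseases = dataset.diseases()
    folds = _fold_assignment(diseases, k, rng, stratified)

    n = dataset.n_samples
    oof_cics = np.zeros((n, arch.cic_dim))
    tissue_pred = np.empty(n, dtype=object)
    disease_pred = np.empty(n, dtype=object)
    tissue_reports, disease_reports = [], []
    for f in range(k):
        test_idx = np.flatnonzero(folds == f)
        train_idx = np.flatnonzero(folds != f)
        n_train = (len(train_idx) // arch.batch_size) * arch.batch_size
        if n_train < arch.batch_size:
            raise ValueError("training fold smaller than one batch")
        if n_train < len(train_idx):
            drop = rng.choice(len(train_idx), size=len(train_idx) - n_train, replace=False)
            train_idx = np.delete(train_idx, drop)
        train_ds = dataset.subset(train_idx)
        test_ds = dataset.subset(test_idx)
        model = build_model(
            arch,
            n_mrna=dataset.mrna.n_features,
            n_mirna=dataset.mirna.n_features,
            n_tissue=len(dataset.tissue_vocab),
            n_disease=len(dataset.disease_vocab),
            seed=int(rng.integers(2**31)),
            tissue_vocab=dataset.tissue_vocab,
            disease_vocab=dataset.disease_vocab,
        )
        fold_cfg = TrainingConfig(
            epochs=config.epochs,
            learning_rate=config.learning_rate,
            weights=config.weights,
            seed=int(rng.integers(2**31)),
        )
        model, _ = fit(model, train_ds, None, fold_cfg, record_history=False)
        out = predict(model, test_ds.mrna.values)
        oof_cics[test_idx] = out.cic
        t_pred = np.array([model.tissue_vocab[i] for i in out.tissue_hat.argmax(1)])
        d_pred = np.array([model.disease_vocab[i] for i in out.disease_hat.argmax(1)])
        tissue_pred[test_idx] = t_pred
        disease_pred[test_idx] = d_pred
        tissue_reports.append(
            classification_report(test_ds.tissues(), t_pred, dataset.tissue_vocab)
        )
        disease_reports.append(
            classification_report(test_ds.diseases(), d_pred, dataset.disease_vocab)
        )
        logger.info(
            "fold %d/%d: tissue %.3f disease %.3f (balanced)",
            f + 1,
            k,
            tissue_reports[-1].balanced_accuracy,
            disease_reports[-1].balanced_accuracy,
        )

    tissues = dataset.tissues()
    pooled_tissue = classification_report(tissues, tissue_pred.astype(str), dataset.tissue_vocab)
    pooled_disease = classification_report(
        diseases, disease_pred.astype(str), dataset.disease_vocab
    )
    ids = list(dataset.sample_ids)
    return CrossValidationResult(
        fold_assignment=pd.Series(folds, index=pd.Index(ids, name="sample_id"), name="fold"),
        tissue_reports=tissue_reports,
        disease_reports=disease_reports,
        pooled_tissue_report=pooled_tissue,
        pooled_disease_report=pooled_disease,
        oof_cics=pd.DataFrame(
            oof_cics,
            index=pd.Index(ids, name="sample_id"),
            columns=[f"cic_{j}" for j in range(arch.cic_dim)],
        ),
        pooled_predictions=pd.DataFrame(
            {
                "sample_id": ids,
                "true_tissue": tissues,
                "pred_tissue": tissue_pred.astype(str),
                "true_disease": diseases,
                "pred_disease": disease_pred.astype(str),
                "fold": folds,
            }
        ),
    )
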