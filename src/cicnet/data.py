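"""Containers and I/O for expression matrices, annotations and preprocessing.

The conventions used throughout the package: samples are rows, features
are columns; expression values are nonnegative and, after max-norm
normalization, lie in [0, 1].
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "PairedDataset",
    "DataSplit",
    "read_expression_table",
    "write_expression_table",
    "read_annotations",
    "match_paired_samples",
    "remove_features",
    "max_norm_normalize",
    "split_and_trim",
    "encode_labels",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A samples x features nonnegative expression matrix with identifiers."""

    values: np.ndarray
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    normalized: bool = False
    norm_axis: str | None = None  # "sample" or "feature" when normalized

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values contain NaN or Inf")
        for name, ids, dim in (
            ("sample", self.sample_ids, values.shape[0]),
            ("feature", self.feature_ids, values.shape[1]),
        ):
            if len(ids) != dim:
                raise ValueError(f"{name}_ids length {len(ids)} != matrix dim {dim}")
            dupes = _duplicates(ids)
            if dupes:
                raise ValueError(f"duplicate {name} IDs: {sorted(dupes)}")
        if values.size and values.min() < 0:
            raise ValueError("expression values must be nonnegative")
        if self.normalized and values.size and values.max() > 1.0 + 1e-12:
            raise ValueError("normalized matrix has values above 1")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, indices: np.ndarray) -> "ExpressionMatrix":
        indices = np.asarray(indices)
        return replace(
            self,
            values=self.values[indices],
            sample_ids=tuple(self.sample_ids[i] for i in indices),
        )


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample ground-truth labels: tissue of origin and disease state."""

    sample_id: str
    tissue: str
    disease: str


@dataclass(frozen=True)
class PairedDataset:
    """Aligned mRNA and miRNA matrices with annotations for the same samples."""

    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    annotations: tuple[SampleAnnotation, ...]
    tissue_vocab: tuple[str, ...]
    disease_vocab: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "annotations", tuple(self.annotations))
        object.__setattr__(self, "tissue_vocab", tuple(self.tissue_vocab))
        object.__setattr__(self, "disease_vocab", tuple(self.disease_vocab))
        ids = [a.sample_id for a in self.annotations]
        if not (tuple(ids) == self.mrna.sample_ids == self.mirna.sample_ids):
            raise ValueError("sample_id order differs between mRNA, miRNA and annotations")
        shared = set(self.mrna.feature_ids) & set(self.mirna.feature_ids)
        if shared:
            raise ValueError(f"feature IDs shared between mRNA and miRNA: {sorted(shared)[:5]}")
        for a in self.annotations:
            if a.tissue not in self.tissue_vocab:
                raise ValueError(f"tissue label {a.tissue!r} not in vocabulary")
            if a.disease not in self.disease_vocab:
                raise ValueError(f"disease label {a.disease!r} not in vocabulary")

    @property
    def n_samples(self) -> int:
        return self.mrna.n_samples

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return self.mrna.sample_ids

    def tissues(self) -> np.ndarray:
        return np.array([a.tissue for a in self.annotations])

    def diseases(self) -> np.ndarray:
        return np.array([a.disease for a in self.annotations])

    def subset(self, indices: np.ndarray) -> "PairedDataset":
        indices = np.asarray(indices)
        return PairedDataset(
            mrna=self.mrna.subset_samples(indices),
            mirna=self.mirna.subset_samples(indices),
            annotations=tuple(self.annotations[i] for i in indices),
            tissue_vocab=self.tissue_vocab,
            disease_vocab=self.disease_vocab,
        )


@dataclass(frozen=True)
class DataSplit:
    """Disjoint train/test index sets into a retained dataset."""

    train_indices: np.ndarray
    test_indices: np.ndarray

    def __post_init__(self):
        train = np.asarray(self.train_indices, dtype=np.intp)
        test = np.asarray(self.test_indices, dtype=np.intp)
        object.__setattr__(self, "train_indices", train)
        object.__setattr__(self, "test_indices", test)
        if np.intersect1d(train, test).size:
            raise ValueError("train and test indices overlap")


def _duplicates(items) -> set:
    seen, dup = set(), set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------------------
# I/O


def read_expression_table(path, orientation: str = "samples_as_rows") -> ExpressionMatrix:
    """Read a delimited expression table into samples x features orientation.

    The file must have one header row and one leading ID column; the
    delimiter is inferred from the extension (.csv -> comma, else tab).
    ``orientation`` states what the file's *rows* are.
    """
    if orientation not in ("samples_as_rows", "features_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    for d in (_duplicates(df.index), _duplicates(df.columns)):
        if d:
            raise ValueError(f"duplicate IDs in {path.name}: {sorted(d)}")
    bad = df.map(lambda v: not isinstance(v, (int, float, np.number)))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r} in {path.name}"
        )
    values = df.to_numpy(dtype=np.float64)
    if orientation == "features_as_rows":
        values = values.T
        sample_ids, feature_ids = tuple(map(str, df.columns)), tuple(map(str, df.index))
    else:
        sample_ids, feature_ids = tuple(map(str, df.index)), tuple(map(str, df.columns))
    if np.isfinite(values).all() and values.size and values.min() < 0:
        r, c = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative expression value at sample {sample_ids[r]!r}, feature {feature_ids[c]!r}"
        )
    return ExpressionMatrix(values, sample_ids, feature_ids)


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    """Write samples-as-rows delimited text; inverse of :func:`read_expression_table`."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    pd.DataFrame(
        matrix.values, index=list(matrix.sample_ids), columns=list(matrix.feature_ids)
    ).to_csv(path, sep=sep, float_format="%.17g")  # %.17g round-trips float64 exactly


def read_annotations(path) -> list[SampleAnnotation]:
    """Read a sample_id/tissue/disease annotation table (TSV or CSV)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"sample_id", "tissue", "disease"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    dupes = _duplicates(df["sample_id"])
    if dupes:
        raise ValueError(f"duplicate sample IDs in annotations: {sorted(dupes)}")
    return [
        SampleAnnotation(str(r.sample_id), str(r.tissue), str(r.disease))
        for r in df.itertuples()
    ]


def write_dataset(dataset: PairedDataset, outdir) -> None:
    """Serialize a paired dataset to TSV tables plus a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression_table(dataset.mrna, outdir / "mrna.tsv")
    write_expression_table(dataset.mirna, outdir / "mirna.tsv")
    pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in dataset.annotations],
            "tissue": [a.tissue for a in dataset.annotations],
            "disease": [a.disease for a in dataset.annotations],
        }
    ).to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    meta = {
        "tissue_vocab": list(dataset.tissue_vocab),
        "disease_vocab": list(dataset.disease_vocab),
        "mrna_normalized": dataset.mrna.normalized,
        "mirna_normalized": dataset.mirna.normalized,
        "mrna_norm_axis": dataset.mrna.norm_axis,
        "mirna_norm_axis": dataset.mirna.norm_axis,
    }
    (outdir / "dataset.json").write_text(json.dumps(meta, indent=2))


def read_dataset(indir) -> PairedDataset:
    indir = Path(indir)
    meta = json.loads((indir / "dataset.json").read_text())
    mrna = read_expression_table(indir / "mrna.tsv")
    mirna = read_expression_table(indir / "mirna.tsv")
    mrna = replace(mrna, normalized=meta["mrna_normalized"], norm_axis=meta["mrna_norm_axis"])
    mirna = replace(mirna, normalized=meta["mirna_normalized"], norm_axis=meta["mirna_norm_axis"])
    annotations = read_annotations(indir / "annotations.tsv")
    return PairedDataset(
        mrna, mirna, annotations, tuple(meta["tissue_vocab"]), tuple(meta["disease_vocab"])
    )


# ---------------------------------------------------------------------------
# Preprocessing


def match_paired_samples(
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    annotations: list[SampleAnnotation],
) -> PairedDataset:
    """Keep the intersection of sample IDs present in all three inputs.

    Samples are reordered consistently (mRNA order is preserved for the
    kept IDs).  The number kept and dropped is logged.
    """
    ann_by_id = {a.sample_id: a for a in annotations}
    mirna_pos = {s: i for i, s in enumerate(mirna.sample_ids)}
    kept = [s for s in mrna.sample_ids if s in mirna_pos and s in ann_by_id]
    if not kept:
        raise ValueError("no sample IDs shared between mRNA, miRNA and annotations")
    n_all = len(set(mrna.sample_ids) | set(mirna.sample_ids) | set(ann_by_id))
    logger.info("matched %d samples (%d dropped)", len(kept), n_all - len(kept))
    mrna_pos = {s: i for i, s in enumerate(mrna.sample_ids)}
    mrna_sub = mrna.subset_samples(np.array([mrna_pos[s] for s in kept]))
    mirna_sub = mirna.subset_samples(np.array([mirna_pos[s] for s in kept]))
    anns = tuple(ann_by_id[s] for s in kept)
    tissue_vocab = tuple(sorted({a.tissue for a in anns}))
    disease_vocab = tuple(sorted({a.disease for a in anns}))
    return PairedDataset(mrna_sub, mirna_sub, anns, tissue_vocab, disease_vocab)


def remove_features(matrix: ExpressionMatrix, feature_ids) -> tuple[ExpressionMatrix, int]:
    """Drop the listed features (e.g. miRNA-encoding genes from the mRNA table).

    Absent IDs are ignored with a warning.  Returns the reduced matrix and
    the number of features actually removed.
    """
    drop = set(feature_ids)
    absent = drop - set(matrix.feature_ids)
    if absent:
        warnings.warn(f"{len(absent)} feature IDs to remove were not present", stacklevel=2)
    keep = [i for i, f in enumerate(matrix.feature_ids) if f not in drop]
    if not keep:
        raise ValueError("removing these features would leave an empty matrix")
    removed = matrix.n_features - len(keep)
    out = replace(
        matrix,
        values=matrix.values[:, keep],
        feature_ids=tuple(matrix.feature_ids[i] for i in keep),
    )
    return out, removed


def max_norm_normalize(matrix: ExpressionMatrix, axis: str = "sample") -> ExpressionMatrix:
    """Scale rows (or columns) into [0, 1] by dividing by their maximum.

    ``axis="sample"`` divides each sample row by its own maximum so the
    largest expressed feature of every sample becomes 1; ``axis="feature"``
    divides each column by the feature's maximum instead.  All-zero rows
    (or columns) are left at zero with a warning.
    """
    if axis not in ("sample", "feature"):
        raise ValueError(f"axis must be 'sample' or 'feature', got {axis!r}")
    if matrix.values.size and matrix.values.min() < 0:
        raise ValueError("max-norm normalization requires nonnegative values")
    ax = 1 if axis == "sample" else 0
    maxima = matrix.values.max(axis=ax, keepdims=True)
    zero = maxima == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero {axis}(s) left unscaled", stacklevel=2)
    scaled = matrix.values / np.where(zero, 1.0, maxima)
    return replace(matrix, values=scaled, normalized=True, norm_axis=axis)


def split_and_trim(
    dataset: PairedDataset,
    test_fraction: float = 0.1,
    batch_size: int = 1,
    seed: int = 0,
) -> tuple[DataSplit, PairedDataset]:
    """Trim to a batch-size multiple, then stratified train/test split.

    The total is first trimmed to the largest multiple of ``batch_size``
    by removing a seeded uniform random subset.  The retained samples are
    split into test (about ``test_fraction``) and train, stratified by
    disease label where class sizes permit, and each partition is then
    trimmed down to the nearest batch-size multiple.  Returns the split
    (indices into the retained dataset) together with the retained dataset.
    """
    n = dataset.n_samples
    if not 0.0 < test_fraction < 1.0:
        # test_fraction ~ 0 is allowed as "no test set" convenience
        if test_fraction != 0.0:
            raise ValueError("test_fraction must lie in [0, 1)")
    if batch_size < 1 or batch_size > n:
        raise ValueError(f"batch_size {batch_size} must be in [1, {n}]")
    rng = np.random.default_rng(seed)
    n_keep = (n // batch_size) * batch_size
    keep = np.sort(rng.choice(n, size=n_keep, replace=False))
    retained = dataset.subset(keep)

    if test_fraction == 0.0:
        split = DataSplit(np.arange(n_keep), np.array([], dtype=np.intp))
        return split, retained

    n_test_target = int(round(n_keep * test_fraction))
    n_test = max((n_test_target // batch_size) * batch_size, batch_size)
    test_idx = _stratified_choice(retained.diseases(), n_test, rng)
    train_idx = np.setdiff1d(np.arange(n_keep), test_idx)
    n_train = (len(train_idx) // batch_size) * batch_size
    if n_train < len(train_idx):
        drop = rng.choice(len(train_idx), size=len(train_idx) - n_train, replace=False)
        train_idx = np.delete(train_idx, drop)
    return DataSplit(np.sort(train_idx), np.sort(test_idx)), retained


def _stratified_choice(labels: np.ndarray, n_pick: int, rng) -> np.ndarray:
    """Pick ``n_pick`` indices approximately proportionally per label class."""
    classes, counts = np.unique(labels, return_counts=True)
    frac = n_pick / len(labels)
    picked: list[np.ndarray] = []
    for cls, cnt in zip(classes, counts):
        idx = np.flatnonzero(labels == cls)
        k = min(cnt, int(round(cnt * frac)))
        picked.append(rng.choice(idx, size=k, replace=False))
    out = np.concatenate(picked) if picked else np.array([], dtype=np.intp)
    # adjust rounding drift by adding/removing uniformly at random
    if len(out) < n_pick:
        pool = np.setdiff1d(np.arange(len(labels)), out)
        out = np.concatenate([out, rng.choice(pool, size=n_pick - len(out), replace=False)])
    elif len(out) > n_pick:
        out = rng.choice(out, size=n_pick, replace=False)
    return np.sort(out)


def encode_labels(labels, vocab) -> np.ndarray:
    """One-hot encode labels against an ordered vocabulary (rows sum to 1)."""
    vocab = list(vocab)
    pos = {v: i for i, v in enumerate(vocab)}
    out = np.zeros((len(labels), len(vocab)))
    for i, lab in enumerate(labels):
        if lab not in pos:
            raise ValueError(f"label {lab!r} not in vocabulary {vocab}")
        out[i, pos[lab]] = 1.0
    return out
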