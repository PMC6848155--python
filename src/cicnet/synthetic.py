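"""Synthetic paired mRNA/miRNA cohorts with tissue -> disease label structure.

Each disease class lives in a latent "cell state" space: a class center is
drawn once, samples scatter around it, and both expression modalities are
smooth nonlinear (softplus) images of the same latent state plus
observation noise.  This gives datasets where (a) disease and tissue are
recoverable from expression, (b) the miRNA profile is a learnable function
of the mRNA profile through the shared latent state, and (c) class
imbalance and hierarchical labels mirror pan-cancer cohorts (many diseases
per tissue, one "Normal" class).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import ExpressionMatrix, PairedDataset, SampleAnnotation, max_norm_normalize

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "generate",
    "inject_missing",
    "inject_gaussian_noise",
    "tiny_preset",
    "paper_shaped_preset",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the cohort generator.

    diseases_per_tissue maps each tissue label to its disease labels (one
    may be "Normal"); n_samples_per_class maps disease label -> count.
    center_scale controls between-class separation in latent space,
    within_class_sd the scatter of samples around their class center, and
    observation_noise_sd the additive noise on expression values before
    normalization.
    """

    diseases_per_tissue: dict[str, tuple[str, ...]]
    n_samples_per_class: dict[str, int]
    n_mrna: int = 300
    n_mirna: int = 40
    true_latent_dim: int = 8
    center_scale: float = 3.0
    within_class_sd: float = 0.5
    observation_noise_sd: float = 0.05
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        diseases = [d for ds in self.diseases_per_tissue.values() for d in ds]
        if len(diseases) != len(set(diseases)):
            raise ValueError("disease labels must be unique across tissues")
        if set(diseases) != set(self.n_samples_per_class):
            raise ValueError(
                "n_samples_per_class keys must match the diseases in diseases_per_tissue"
            )
        if any(n <= 0 for n in self.n_samples_per_class.values()):
            raise ValueError("all class sample counts must be positive")
        if min(self.n_mrna, self.n_mirna, self.true_latent_dim) <= 0:
            raise ValueError("dimensions must be positive")
        if self.within_class_sd < 0 or self.observation_noise_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if not 0.0 <= self.missing_fraction <= 0.9:
            raise ValueError("missing_fraction must lie in [0, 0.9]")


@dataclass(frozen=True)
class SyntheticDataset:
    dataset: PairedDataset
    true_latent: np.ndarray
    config: GeneratorConfig


def tiny_preset(seed: int = 0, **overrides) -> GeneratorConfig:
    """Desk-scale default: 4 tissues x 2 diseases, 100 samples/class,
    300 mRNA + 40 miRNA features, 8-D latent state."""
    tissues = {
        "Lung": ("LungAdeno", "LungSquamous"),
        "Kidney": ("KidneyClear", "KidneyPapillary"),
        "Colon": ("ColonAdeno", "Normal"),
        "Brain": ("Glioblastoma", "LowGradeGlioma"),
    }
    counts = {d: 100 for ds in tissues.values() for d in ds}
    cfg = GeneratorConfig(diseases_per_tissue=tissues, n_samples_per_class=counts, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


def imbalanced_preset(seed: int = 0) -> GeneratorConfig:
    """Tiny preset with strong class imbalance (rarest class 12 samples)."""
    cfg = tiny_preset(seed)
    counts = dict(cfg.n_samples_per_class)
    sizes = [220, 160, 120, 90, 60, 40, 25, 12]
    for d, n in zip(sorted(counts), sizes):
        counts[d] = n
    return replace(cfg, n_samples_per_class=counts)


def paper_shaped_preset(seed: int = 0) -> GeneratorConfig:
    """A cohort with the full label structure of a pan-cancer compendium:
    27 tissues, 34 disease classes (33 cancers + Normal), imbalanced class
    sizes, 19671 mRNA and 2588 miRNA features.  Heavy; not the default."""
    rng = np.random.default_rng(seed)
    tissues: dict[str, tuple[str, ...]] = {}
    diseases: list[str] = []
    # 4 tissues with 2-3 cancer types, the rest with one, plus Normal
    multi = {"Tissue01": 3, "Tissue02": 2, "Tissue03": 2, "Tissue04": 2}
    k = 0
    for i in range(1, 28):
        t = f"Tissue{i:02d}"
        n_dis = multi.get(t, 1)
        ds = []
        for _ in range(n_dis):
            if len(diseases) < 33:
                k += 1
                ds.append(f"Cancer{k:02d}")
                diseases.append(ds[-1])
        if t == "Tissue01":
            ds.append("Normal")
        tissues[t] = tuple(ds)
    counts = {d: int(rng.integers(30, 900)) for d in diseases}
    counts["Normal"] = 626
    return GeneratorConfig(
        diseases_per_tissue=tissues,
        n_samples_per_class=counts,
        n_mrna=19671,
        n_mirna=2588,
        seed=seed,
    )


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Draw a cohort from the generator; bit-reproducible given the seed."""
    rng = np.random.default_rng(config.seed)
    d = config.true_latent_dim

    classes: list[tuple[str, str]] = [
        (t, dis) for t, ds in config.diseases_per_tissue.items() for dis in ds
    ]
    centers = {dis: config.center_scale * rng.standard_normal(d) for _, dis in classes}

    # fixed loading matrices shared by all samples
    A = rng.standard_normal((d, config.n_mrna)) / np.sqrt(d)
    a = rng.standard_normal(config.n_mrna) * 0.5
    B = rng.standard_normal((d, config.n_mirna)) / np.sqrt(d)
    b = rng.standard_normal(config.n_mirna) * 0.5

    latents, anns = [], []
    for tissue, disease in classes:
        n = config.n_samples_per_class[disease]
        z = centers[disease] + config.within_class_sd * rng.standard_normal((n, d))
        latents.append(z)
        anns.extend((tissue, disease) for _ in range(n))
    Z = np.concatenate(latents, axis=0)

    def softplus(x):
        return np.logaddexp(0.0, x)

    mrna = softplus(Z @ A + a)
    mirna = softplus(Z @ B + b)
    if config.observation_noise_sd > 0:
        mrna = np.clip(mrna + config.observation_noise_sd * rng.standard_normal(mrna.shape), 0, None)
        mirna = np.clip(mirna + config.observation_noise_sd * rng.standard_normal(mirna.shape), 0, None)

    ids = tuple(f"S{i:05d}" for i in range(len(Z)))
    mrna_feats = tuple(f"gene_{j}" for j in range(config.n_mrna))
    mirna_feats = tuple(f"mir_{j}" for j in range(config.n_mirna))
    mrna_m = max_norm_normalize(ExpressionMatrix(mrna, ids, mrna_feats))
    mirna_m = max_norm_normalize(ExpressionMatrix(mirna, ids, mirna_feats))
    if config.missing_fraction > 0:
        mrna_m = inject_missing(mrna_m, config.missing_fraction, seed=config.seed + 1)

    annotations = tuple(
        SampleAnnotation(ids[i], anns[i][0], anns[i][1]) for i in range(len(ids))
    )
    tissue_vocab = tuple(sorted(config.diseases_per_tissue))
    disease_vocab = tuple(sorted(config.n_samples_per_class))
    dataset = PairedDataset(mrna_m, mirna_m, annotations, tissue_vocab, disease_vocab)
    return SyntheticDataset(dataset, Z, config)


def inject_missing(matrix: ExpressionMatrix, fraction: float, seed: int = 0) -> ExpressionMatrix:
    """Zero out exactly round(fraction * n_entries) uniformly chosen entries."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if fraction == 0.0:
        return matrix
    rng = np.random.default_rng(seed)
    n = matrix.values.size
    k = int(round(fraction * n))
    flat = rng.choice(n, size=k, replace=False)
    values = matrix.values.copy()
    values.flat[flat] = 0.0
    return replace(matrix, values=values)


def inject_gaussian_noise(
    matrix: ExpressionMatrix, sd: float, seed: int = 0, clip_nonnegative: bool = False
) -> ExpressionMatrix:
    """Add zero-mean i.i.d. Gaussian noise to every entry.

    By default the result is left unclipped, matching an additive noise
    layer; the normalized flag is dropped because values may leave [0, 1].
    Pass ``clip_nonnegative=True`` to clamp at zero.
    """
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    if sd == 0:
        return matrix
    rng = np.random.default_rng(seed)
    values = matrix.values + sd * rng.standard_normal(matrix.values.shape)
    if clip_nonnegative:
        values = np.clip(values, 0.0, None)
        return replace(matrix, values=values, normalized=False, norm_axis=None)
    # bypass the nonnegativity invariant of ExpressionMatrix deliberately:
    # an additive-noise corruption is allowed to go below zero
    out = ExpressionMatrix.__new__(ExpressionMatrix)
    object.__setattr__(out, "values", values)
    object.__setattr__(out, "sample_ids", matrix.sample_ids)
    object.__setattr__(out, "feature_ids", matrix.feature_ids)
    object.__setattr__(out, "normalized", False)
    object.__setattr__(out, "norm_axis", None)
    return out
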