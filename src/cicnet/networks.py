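"""The four multi-task autoencoder architectures.

Every network compresses an mRNA expression profile into a low-dimensional
cell identity code (CIC) and decodes it into four outputs: the
reconstructed mRNA profile, a predicted miRNA profile, a tissue-of-origin
class and a disease-state class.  Two regularization families are
provided — contractive (CAE) and variational (VAE) — each with an
optional dropout variant that corrupts the input and every encoder layer
during training.

Building layers follow the pattern batch-normalization -> dense ->
activation.  In inference mode all stochastic layers (input noise,
dropout, the VAE sampling step) are disabled, so the forward pass is a
deterministic function of the parameters and the input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

__all__ = [
    "ArchitectureConfig",
    "BatchNormParams",
    "ModelState",
    "ForwardOutputs",
    "build_model",
    "encode",
    "decode",
    "predict",
    "batch_norm_forward",
    "corruption_layers",
    "n_parameters",
    "save_model",
    "load_model",
]

KINDS = ("CAE", "DropoutCAE", "VAE", "DropoutVAE")
ACTIVATIONS = ("relu", "linear", "softplus")
BN_EPS = 1e-3
BN_MOMENTUM = 0.9


@dataclass(frozen=True)
class ArchitectureConfig:
    """One point in the architecture hyperparameter space."""

    kind: str = "DropoutCAE"
    encoder_units: tuple[int, ...] = (64, 32)
    decoder_units: tuple[int, ...] = (32, 64)
    cic_dim: int = 8
    activation: str = "softplus"
    dropout_kind: str = "bernoulli"  # bernoulli | gaussian | none
    dropout_rate: float = 0.25
    input_noise_sd: float = 0.0
    batch_size: int = 50

    def __post_init__(self):
        object.__setattr__(self, "encoder_units", tuple(int(u) for u in self.encoder_units))
        object.__setattr__(self, "decoder_units", tuple(int(u) for u in self.decoder_units))
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")
        if not self.encoder_units or not self.decoder_units:
            raise ValueError("encoder and decoder need at least one building layer")
        if list(self.encoder_units) != sorted(self.encoder_units, reverse=True):
            raise ValueError("encoder_units must be non-increasing")
        if list(self.decoder_units) != sorted(self.decoder_units):
            raise ValueError("decoder_units must be non-decreasing")
        if self.cic_dim < 1 or self.cic_dim > min(self.encoder_units):
            raise ValueError("cic_dim must be in [1, min(encoder_units)]")
        if not self.has_dropout:
            if self.dropout_rate not in (0, 0.0) and self.dropout_kind != "none":
                raise ValueError(f"{self.kind} does not take dropout layers")
        if self.dropout_kind not in ("bernoulli", "gaussian", "none"):
            raise ValueError("dropout_kind must be bernoulli, gaussian or none")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.input_noise_sd < 0:
            raise ValueError("input_noise_sd must be nonnegative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")

    @property
    def is_variational(self) -> bool:
        return self.kind in ("VAE", "DropoutVAE")

    @property
    def has_dropout(self) -> bool:
        return self.kind in ("DropoutCAE", "DropoutVAE")


@dataclass
class BatchNormParams:
    """Learned scale/shift plus running statistics of one normalization layer."""

    gamma: np.ndarray
    beta: np.ndarray
    epsilon: float = BN_EPS
    running_mean: np.ndarray = None
    running_var: np.ndarray = None

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.running_mean is None:
            self.running_mean = np.zeros_like(np.asarray(self.gamma, dtype=float))
        if self.running_var is None:
            self.running_var = np.ones_like(np.asarray(self.gamma, dtype=float))


@dataclass
class ModelState:
    """Trained (or freshly initialized) parameters of one architecture."""

    config: ArchitectureConfig
    n_mrna: int
    n_mirna: int
    tissue_vocab: tuple[str, ...]
    disease_vocab: tuple[str, ...]
    params: dict[str, Tensor]
    running: dict[str, np.ndarray]
    seed: int
    trained: bool = False

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


@dataclass
class ForwardOutputs:
    """Numpy outputs of a full deterministic forward pass."""

    cic: np.ndarray
    mrna_hat: np.ndarray
    mirna_hat: np.ndarray
    tissue_hat: np.ndarray
    disease_hat: np.ndarray
    mu_z: np.ndarray | None = None
    logvar_z: np.ndarray | None = None


# ---------------------------------------------------------------------------
# construction


def _glorot(rng, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def build_model(
    config: ArchitectureConfig,
    n_mrna: int,
    n_mirna: int,
    n_tissue: int,
    n_disease: int | None = None,
    seed: int = 0,
    tissue_vocab: tuple[str, ...] | None = None,
    disease_vocab: tuple[str, ...] | None = None,
) -> ModelState:
    """Initialize all parameters of one architecture (seeded Glorot)."""
    if tissue_vocab is None:
        tissue_vocab = tuple(f"tissue_{i}" for i in range(n_tissue))
    if disease_vocab is None:
        disease_vocab = tuple(f"disease_{i}" for i in range(n_disease or 0))
    n_tissue, n_disease = len(tissue_vocab), len(disease_vocab)
    if min(n_mrna, n_mirna, n_tissue, n_disease) < 1:
        raise ValueError("all dimensions must be positive")
    rng = np.random.default_rng(seed)
    params: dict[str, Tensor] = {}
    running: dict[str, np.ndarray] = {}

    def add_bn(name: str, dim: int):
        params[f"{name}_gamma"] = ad.parameter(np.ones(dim))
        params[f"{name}_beta"] = ad.parameter(np.zeros(dim))
        running[f"{name}_mean"] = np.zeros(dim)
        running[f"{name}_var"] = np.ones(dim)

    def add_dense(name: str, d_in: int, d_out: int):
        params[f"{name}_W"] = ad.parameter(_glorot(rng, d_in, d_out))
        params[f"{name}_b"] = ad.parameter(np.zeros(d_out))

    d = n_mrna
    for i, u in enumerate(config.encoder_units):
        add_bn(f"enc{i}_bn", d)
        add_dense(f"enc{i}", d, u)
        d = u
    add_bn("cic_bn", d)
    if config.is_variational:
        add_dense("cic_mu", d, config.cic_dim)
        add_dense("cic_logvar", d, config.cic_dim)
    else:
        add_dense("cic", d, config.cic_dim)

    d = config.cic_dim
    for i, u in enumerate(config.decoder_units):
        add_bn(f"dec{i}_bn", d)
        add_dense(f"dec{i}", d, u)
        d = u
    for head, width in (
        ("head_mrna", n_mrna),
        ("head_mirna", n_mirna),
        ("head_tissue", n_tissue),
        ("head_disease", n_disease),
    ):
        add_dense(head, d, width)

    return ModelState(
        config=config,
        n_mrna=n_mrna,
        n_mirna=n_mirna,
        tissue_vocab=tuple(tissue_vocab),
        disease_vocab=tuple(disease_vocab),
        params=params,
        running=running,
        seed=seed,
    )


def n_parameters(model: ModelState) -> int:
    return sum(p.data.size for p in model.params.values())


# ---------------------------------------------------------------------------
# layers


def batch_norm_forward(
    x_batch: np.ndarray, params: BatchNormParams, training: bool
) -> np.ndarray:
    """Normalize a batch per feature: gamma * (x - mu)/sqrt(var + eps) + beta.

    Training mode uses the mini-batch statistics and updates the running
    statistics in place; inference mode uses the running statistics.
    """
    x = np.asarray(x_batch, dtype=float)
    if training:
        if x.shape[0] < 2:
            raise ValueError("batch normalization in training mode needs batch size >= 2")
        mu = x.mean(axis=0)
        var = x.var(axis=0)
        params.running_mean = BN_MOMENTUM * params.running_mean + (1 - BN_MOMENTUM) * mu
        params.running_var = BN_MOMENTUM * params.running_var + (1 - BN_MOMENTUM) * var
    else:
        mu, var = params.running_mean, params.running_var
    return params.gamma * (x - mu) / np.sqrt(var + params.epsilon) + params.beta


def corruption_layers(
    X: np.ndarray,
    kind: str,
    parameter: float,
    training: bool,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Stochastic corruption used by the denoising objective.

    ``gaussian_noise`` adds N(0, parameter^2); ``bernoulli_dropout`` keeps
    each unit with probability 1-rate and rescales kept units by
    1/(1-rate) (inverted scaling, so inference is identity);
    ``gaussian_dropout`` multiplies by N(1, rate/(1-rate)).  In inference
    mode all kinds are the identity.
    """
    X = np.asarray(X, dtype=float)
    if not training:
        return X
    if rng is None:
        rng = np.random.default_rng(seed)
    if kind == "gaussian_noise":
        if parameter < 0:
            raise ValueError("noise sd must be nonnegative")
        if parameter == 0:
            return X
        return X + parameter * rng.standard_normal(X.shape)
    if kind == "bernoulli_dropout":
        if not 0.0 <= parameter < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        if parameter == 0:
            return X
        keep = 1.0 - parameter
        mask = rng.random(X.shape) < keep
        return X * mask / keep
    if kind == "gaussian_dropout":
        if not 0.0 <= parameter < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        if parameter == 0:
            return X
        sigma = np.sqrt(parameter / (1.0 - parameter))
        return X * (1.0 + sigma * rng.standard_normal(X.shape))
    raise ValueError(f"unknown corruption kind {kind!r}")


_ACT = {"relu": ad.relu, "softplus": ad.softplus, "linear": lambda t: t}


def _act_deriv(name: str, pre: Tensor) -> Tensor | None:
    """Derivative of the activation at the pre-activation, as a graph node."""
    if name == "linear":
        return None
    if name == "relu":
        return ad.constant((pre.data > 0).astype(float))
    return ad.sigmoid(pre)  # softplus'


def _bn_graph(
    model: ModelState, name: str, x: Tensor, training: bool
) -> tuple[Tensor, Tensor]:
    """Batch-norm as a graph node; returns (output, per-feature scale).

    The scale gamma/sqrt(var+eps) is returned for Jacobian assembly; the
    variance in the scale is detached (treated as a constant of the batch).
    """
    gamma = model.params[f"{name}_gamma"]
    beta = model.params[f"{name}_beta"]
    if training:
        if x.shape[0] < 2:
            raise ValueError("batch normalization in training mode needs batch size >= 2")
        mu = x.mean(axis=0, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
        model.running[f"{name}_mean"] = (
            BN_MOMENTUM * model.running[f"{name}_mean"] + (1 - BN_MOMENTUM) * mu.data.ravel()
        )
        model.running[f"{name}_var"] = (
            BN_MOMENTUM * model.running[f"{name}_var"] + (1 - BN_MOMENTUM) * var.data.ravel()
        )
        inv = (var + BN_EPS) ** -0.5
        out = gamma * (x - mu) * inv + beta
        scale = gamma * ad.constant(inv.data.ravel())
    else:
        mu = ad.constant(model.running[f"{name}_mean"])
        inv = ad.constant(1.0 / np.sqrt(model.running[f"{name}_var"] + BN_EPS))
        out = gamma * (x - mu) * inv + beta
        scale = gamma * inv
    return out, scale


def encoder_graph(
    model: ModelState,
    X: np.ndarray,
    training: bool,
    rng: np.random.Generator | None = None,
    corrupt: bool = True,
):
    """Run the encoder, returning (cic, mu, logvar, jacobian_cache).

    jacobian_cache holds per building layer the batch-norm scale, the
    dense weight and the activation derivative, from which the per-sample
    input->CIC Jacobian can be assembled (dropout treated as identity).
    """
    cfg = model.config
    x = np.asarray(X, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.n_mrna:
        raise ValueError(f"input must be (batch, {model.n_mrna}), got {x.shape}")
    if training and corrupt:
        if rng is None:
            rng = np.random.default_rng(0)
        if cfg.input_noise_sd > 0:
            x = corruption_layers(x, "gaussian_noise", cfg.input_noise_sd, True, rng=rng)
        if cfg.has_dropout and cfg.dropout_kind != "none":
            x = corruption_layers(
                x, f"{cfg.dropout_kind}_dropout", cfg.dropout_rate, True, rng=rng
            )
    h = ad.constant(x)
    cache: list[tuple[Tensor, Tensor, Tensor | None]] = []
    for i in range(len(cfg.encoder_units)):
        normed, scale = _bn_graph(model, f"enc{i}_bn", h, training)
        pre = normed @ model.params[f"enc{i}_W"] + model.params[f"enc{i}_b"]
        cache.append((scale, model.params[f"enc{i}_W"], _act_deriv(cfg.activation, pre)))
        h = _ACT[cfg.activation](pre)
        if training and cfg.has_dropout and cfg.dropout_kind != "none":
            mask = corruption_layers(
                np.ones(h.shape), f"{cfg.dropout_kind}_dropout", cfg.dropout_rate, True, rng=rng
            )
            h = h * ad.constant(mask)
    normed, scale = _bn_graph(model, "cic_bn", h, training)
    if cfg.is_variational:
        mu = normed @ model.params["cic_mu_W"] + model.params["cic_mu_b"]
        logvar = normed @ model.params["cic_logvar_W"] + model.params["cic_logvar_b"]
        cache.append((scale, model.params["cic_mu_W"], None))
        if training:
            eps = rng.standard_normal(mu.shape) if rng is not None else 0.0
            z = mu + ad.exp(logvar * 0.5) * ad.constant(eps)
        else:
            z = mu
        return z, mu, logvar, cache
    z = normed @ model.params["cic_W"] + model.params["cic_b"]
    cache.append((scale, model.params["cic_W"], None))
    return z, None, None, cache


def jacobian_frobenius_sq(cache) -> Tensor:
    """Mean over the batch of ||d cic / d input||_F^2 from an encoder cache.

    The per-sample Jacobian is the product over building layers of
    diag(bn_scale) @ W @ diag(act'(pre)).  The product is assembled from
    the CIC side inward so the widest (input) dimension enters last, which
    keeps the batched intermediates small.
    """
    batch = 1
    M = None  # accumulates d_layer x cic_dim (optionally batched)
    for scale, W, deriv in reversed(cache):
        if deriv is not None:  # activation derivative sits between W and M
            batch = deriv.shape[0]
            M = deriv.reshape(batch, deriv.shape[1], 1) * M
        A = scale.reshape(W.shape[0], 1) * W
        M = A if M is None else ad.matmul(A, M)
    return (M**2).sum() * (1.0 / batch)


def decoder_graph(model: ModelState, z: Tensor, training: bool):
    """Run the decoder from a CIC batch to the four output heads."""
    cfg = model.config
    h = z
    for i in range(len(cfg.decoder_units)):
        normed, _ = _bn_graph(model, f"dec{i}_bn", h, training)
        pre = normed @ model.params[f"dec{i}_W"] + model.params[f"dec{i}_b"]
        h = _ACT[cfg.activation](pre)
    mrna = ad.sigmoid(h @ model.params["head_mrna_W"] + model.params["head_mrna_b"])
    mirna = ad.sigmoid(h @ model.params["head_mirna_W"] + model.params["head_mirna_b"])
    tissue = ad.softmax(h @ model.params["head_tissue_W"] + model.params["head_tissue_b"], axis=1)
    disease = ad.softmax(
        h @ model.params["head_disease_W"] + model.params["head_disease_b"], axis=1
    )
    return mrna, mirna, tissue, disease


# ---------------------------------------------------------------------------
# public deterministic API


def encode(
    model: ModelState,
    X: np.ndarray,
    stochastic: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Map expression profiles to CICs.

    With ``stochastic=False`` (the default) noise, dropout and the VAE
    sampling step are disabled; for VAE kinds the posterior mean is
    returned.  ``stochastic=True`` draws one reparameterized sample for
    VAE kinds (seeded).
    """
    z, mu, logvar, _ = encoder_graph(model, X, training=False)
    if model.config.is_variational and stochastic:
        rng = np.random.default_rng(seed)
        eps = rng.standard_normal(mu.shape)
        return mu.data + np.exp(0.5 * logvar.data) * eps
    return z.data


def decode(model: ModelState, Z: np.ndarray) -> ForwardOutputs:
    """Decode CICs into the four output heads (deterministic)."""
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[1] != model.config.cic_dim:
        raise ValueError(f"Z must be (batch, {model.config.cic_dim}), got {Z.shape}")
    mrna, mirna, tissue, disease = decoder_graph(model, ad.constant(Z), training=False)
    return ForwardOutputs(
        cic=Z,
        mrna_hat=mrna.data,
        mirna_hat=mirna.data,
        tissue_hat=tissue.data,
        disease_hat=disease.data,
    )


def predict(model: ModelState, X: np.ndarray) -> ForwardOutputs:
    """Full deterministic forward pass: encode then decode."""
    z, mu, logvar, _ = encoder_graph(model, X, training=False)
    mrna, mirna, tissue, disease = decoder_graph(model, z, training=False)
    return ForwardOutputs(
        cic=z.data,
        mrna_hat=mrna.data,
        mirna_hat=mirna.data,
        tissue_hat=tissue.data,
        disease_hat=disease.data,
        mu_z=None if mu is None else mu.data,
        logvar_z=None if logvar is None else logvar.data,
    )


# ---------------------------------------------------------------------------
# serialization


def save_model(model: ModelState, outdir) -> None:
    """Write architecture JSON + parameter arrays (npz) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": model.config.__dict__.copy(),
        "n_mrna": model.n_mrna,
        "n_mirna": model.n_mirna,
        "tissue_vocab": list(model.tissue_vocab),
        "disease_vocab": list(model.disease_vocab),
        "seed": model.seed,
        "trained": model.trained,
    }
    (outdir / "model.json").write_text(json.dumps(meta, indent=2, default=list))
    arrays = {f"param/{k}": v.data for k, v in model.params.items()}
    arrays.update({f"running/{k}": v for k, v in model.running.items()})
    np.savez(outdir / "params.npz", **arrays)


def load_model(indir) -> ModelState:
    indir = Path(indir)
    meta = json.loads((indir / "model.json").read_text())
    cfg_dict = meta["config"]
    cfg_dict["encoder_units"] = tuple(cfg_dict["encoder_units"])
    cfg_dict["decoder_units"] = tuple(cfg_dict["decoder_units"])
    config = ArchitectureConfig(**cfg_dict)
    with np.load(indir / "params.npz") as npz:
        params = {
            k.split("/", 1)[1]: ad.parameter(npz[k]) for k in npz.files if k.startswith("param/")
        }
        running = {
            k.split("/", 1)[1]: npz[k].copy() for k in npz.files if k.startswith("running/")
        }
    model = ModelState(
        config=config,
        n_mrna=meta["n_mrna"],
        n_mirna=meta["n_mirna"],
        tissue_vocab=tuple(meta["tissue_vocab"]),
        disease_vocab=tuple(meta["disease_vocab"]),
        params=params,
        running=running,
        seed=meta["seed"],
        trained=meta["trained"],
    )
    return model
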