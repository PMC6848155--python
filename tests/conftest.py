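import numpy as np
import pytest

from cicnet import (
    ArchitectureConfig,
    TrainingConfig,
    build_model,
    fit,
    generate,
    tiny_preset,
)


@pytest.fixture(scope="session")
def tiny_dataset():
    """The default desk-scale cohort: 8 classes x 100 samples, 300+40 features."""
    return generate(tiny_preset(seed=7)).dataset


@pytest.fixture(scope="session")
def tiny_synthetic():
    return generate(tiny_preset(seed=7))


@pytest.fixture(scope="session")
def quick_model(tiny_dataset):
    """A DropoutCAE trained briefly on the tiny cohort — converged enough
    for harness tests that need a trained model, cheap enough for CI."""
    arch = ArchitectureConfig(kind="DropoutCAE", batch_size=50)
    model = build_model(
        arch,
        n_mrna=tiny_dataset.mrna.n_features,
        n_mirna=tiny_dataset.mirna.n_features,
        n_tissue=len(tiny_dataset.tissue_vocab),
        n_disease=len(tiny_dataset.disease_vocab),
        seed=11,
        tissue_vocab=tiny_dataset.tissue_vocab,
        disease_vocab=tiny_dataset.disease_vocab,
    )
    model, _ = fit(
        model,
        tiny_dataset,
        None,
        TrainingConfig(epochs=15, seed=11),
        record_history=False,
    )
    return model


def toy_cae(
    n_in=5,
    encoder_units=(7, 6),
    cic_dim=3,
    activation="softplus",
    seed=0,
    randomize_stats=True,
):
    """A small untrained CAE with randomized batch-norm statistics, so the
    encoder is a generic smooth map (useful for Jacobian oracle checks)."""
    arch = ArchitectureConfig(
        kind="CAE",
        encoder_units=encoder_units,
        decoder_units=tuple(reversed(encoder_units)),
        cic_dim=cic_dim,
        activation=activation,
        dropout_kind="none",
        dropout_rate=0.0,
        batch_size=4,
    )
    model = build_model(arch, n_in, 3, 2, 2, seed=seed)
    if randomize_stats:
        rng = np.random.default_rng(seed + 100)
        for k in model.running:
            model.running[k] = (
                np.abs(rng.normal(1.0, 0.2, model.running[k].shape))
                if k.endswith("var")
                else rng.normal(0.0, 0.3, model.running[k].shape)
            )
        for k, p in model.params.items():
            if k.endswith("gamma"):
                p.data = np.abs(rng.normal(1.0, 0.2, p.data.shape))
            elif k.endswith("beta"):
                p.data = rng.normal(0.0, 0.1, p.data.shape)
    return model


def finite_difference_jacobian_sq(model, X, eps=1e-5):
    """Mean squared Frobenius norm of the input->CIC Jacobian by central
    differences through the public deterministic encoder."""
    from cicnet import encode

    X = np.atleast_2d(X)
    total = 0.0
    for x in X:
        cols = []
        for i in range(len(x)):
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            cols.append((encode(model, xp[None]) - encode(model, xm[None])).ravel() / (2 * eps))
        J = np.stack(cols, axis=1)
        total += (J**2).sum()
    return total / len(X)
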