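# cicnet

Multi-task autoencoders that compress a whole-transcriptome mRNA
expression profile into a low-dimensional **cell identity code (CIC)**
and decode it — simultaneously — into the reconstructed mRNA profile, a
predicted miRNA profile, a tissue-of-origin class and a disease-state
class.  The package is aimed at computational biologists who want to
learn compact, discriminative latent representations of bulk
transcriptomes (e.g. pan-cancer compendia with a tissue → disease label
hierarchy, strong class imbalance and a "Normal" class) and to benchmark
them against classical dimensionality reduction and classifiers.

## The model

An encoder ψ maps a max-norm-normalized profile x ∈ [0,1]^G to the CIC
z = ψ(x); a decoder φ with four heads produces x̃ (mRNA, sigmoid),
the miRNA profile (sigmoid), and tissue/disease probability vectors
(softmax).  Training minimizes the weighted multi-task objective

J = 0.5·(1−cos(y_t, ŷ_t)) + 0.5·(1−cos(y_d, ŷ_d)) + 10⁻³·MSE_mRNA + 10⁻³·MSE_miRNA + R

with regularizer R either the contractive penalty λ‖J_ψ(x)‖²_F
(CAE kinds) or the KL divergence D_KL(q(z|x) ‖ N(0, I)) (VAE kinds).
Four architectures are provided — CAE, Dropout-CAE, VAE, Dropout-VAE —
where the Dropout variants corrupt the input and every encoder layer
during training (Bernoulli or multiplicative-Gaussian dropout plus an
optional additive input-noise layer), realizing a denoising objective.
Building layers are batch-normalization → dense → activation.  A
tree-structured Parzen estimator searches the discrete architecture
space; evaluation uses balanced accuracy, confusion matrices,
sensitivity/specificity, paired McNemar tests and noise/missing-value
robustness sweeps.  A seeded synthetic-cohort generator makes the whole
pipeline testable without external data.

The networks run on a small reverse-mode autodiff engine included in the
package (numpy only); standard analysis steps (PCA variants, baseline
classifiers, t-SNE) use scikit-learn.

## Worked example

```python
from cicnet import (ArchitectureConfig, TrainingConfig, build_model, fit,
                    generate, split_and_trim, tiny_preset)

ds = generate(tiny_preset(seed=7)).dataset      # 800 samples, 300+40 features,
arch = ArchitectureConfig(kind="DropoutCAE")    # 4 tissues x 2 diseases

split, retained = split_and_trim(ds, 0.1, arch.batch_size, seed=0)
model = build_model(arch, ds.mrna.n_features, ds.mirna.n_features,
                    len(ds.tissue_vocab), len(ds.disease_vocab), seed=0,
                    tissue_vocab=ds.tissue_vocab, disease_vocab=ds.disease_vocab)
model, history = fit(model, retained.subset(split.train_indices),
                     retained.subset(split.test_indices),
                     TrainingConfig(epochs=40, seed=0))
print(history.to_frame().iloc[-1][["train_total", "test_tissue_acc", "test_disease_acc"]])
```

Running this (it is `examples/02_train_autoencoder.py`) prints

```
total loss:            0.5076 -> 0.0018
test tissue balanced:  1.000
test disease balanced: 1.000
test mRNA MSE:         0.00259
test miRNA MSE:        0.00382
```

i.e. after 40 epochs the 8-dimensional code supports perfect held-out
tissue and disease classification on the synthetic cohort while
reconstructing both expression modalities with MSE on the order of
10⁻³.  The `examples/` directory holds one short script per capability:
cohort simulation, training, cross-validation, robustness sweeps, TPE
hyperparameter search, and the CIC-vs-PCA comparison.

A thin CLI wraps the same functions for shell pipelines:

```bash
cicnet simulate --preset tiny --seed 7 -o out/sim
cicnet train --data out/sim --kind DropoutCAE --epochs 200 -o out/run
cicnet robustness --model out/run/model --data out/sim -o out/rob
```

Every output directory contains a `manifest.json` with the config and
seed needed to reproduce the run.

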