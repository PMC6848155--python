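"""Train a Dropout contractive autoencoder on the synthetic cohort.

The model encodes each 300-gene mRNA profile into an 8-dimensional cell
identity code (CIC) and decodes it into four outputs: the reconstructed
mRNA profile, the predicted miRNA profile, and tissue/disease classes.
Forty epochs are enough for the desk-scale cohort; the full protocol
uses 200.
"""

from cicnet import (
    ArchitectureConfig,
    TrainingConfig,
    build_model,
    fit,
    generate,
    split_and_trim,
    tiny_preset,
)

ds = generate(tiny_preset(seed=7)).dataset
arch = ArchitectureConfig(kind="DropoutCAE", batch_size=50)

split, retained = split_and_trim(ds, test_fraction=0.1, batch_size=arch.batch_size, seed=0)
train_ds = retained.subset(split.train_indices)
test_ds = retained.subset(split.test_indices)
print(f"train {train_ds.n_samples} / test {test_ds.n_samples} samples")

model = build_model(
    arch,
    n_mrna=ds.mrna.n_features,
    n_mirna=ds.mirna.n_features,
    n_tissue=len(ds.tissue_vocab),
    n_disease=len(ds.disease_vocab),
    seed=0,
    tissue_vocab=ds.tissue_vocab,
    disease_vocab=ds.disease_vocab,
)
model, history = fit(model, train_ds, test_ds, TrainingConfig(epochs=40, seed=0))

df = history.to_frame()
first, last = df.iloc[0], df.iloc[-1]
print(f"\ntotal loss:            {first.train_total:.4f} -> {last.train_total:.4f}")
print(f"test tissue balanced:  {last.test_tissue_acc:.3f}")
print(f"test disease balanced: {last.test_disease_acc:.3f}")
print(f"test mRNA MSE:         {last.test_mrna_mse:.5f}")
print(f"test miRNA MSE:        {last.test_mirna_mse:.5f}")
# The loss falls by orders of magnitude and both held-out balanced
# accuracies approach 1.0: the 8-D code carries the class structure.
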