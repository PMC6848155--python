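"""Bayesian (TPE) search over the discrete architecture space.

Each trial trains a small network for a few epochs on an 80/20 split and
scores it by the average total loss over all data; the TPE surrogate
steers later trials towards the good region.  Twelve trials at reduced
epochs keep this example around a minute.
"""

from cicnet import bayesian_optimize, generate, tiny_preset
from cicnet.hpo import default_architecture_space, hpo_objective

ds = generate(tiny_preset(seed=7)).dataset
space = default_architecture_space("DropoutCAE")
print(f"search space size: {space.size} configurations")


def objective(h):
    return hpo_objective("DropoutCAE", ds, h, reduced_epochs=3, seed=0)


best, history = bayesian_optimize(objective, space, n_iter=12, n_warmup=4, seed=0)

print("\ntrial scores (average total loss, lower is better):")
for i, t in enumerate(history):
    print(f"  {i:2d}  {t.score:.4f}  cic_dim={t.hyperparameters['cic_dim']}, "
          f"act={t.hyperparameters['activation']}")
print(f"\nbest: {best.score:.4f} at {best.hyperparameters}")
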