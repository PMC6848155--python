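"""Bayesian hyperparameter optimization over a finite discrete space.

The optimizer is a tree-structured Parzen estimator (TPE) specialised to
fully categorical search spaces: completed trials are split at the
gamma-quantile of their scores into good and bad sets, per-dimension
categorical densities l(h) (good) and g(h) (bad) are fitted with
add-one smoothing, and the next trial is the candidate (drawn from l)
that maximizes the ratio l(h)/g(h).  Random search and exhaustive grid
search are provided as baselines with the same return contract.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .data import PairedDataset, split_and_trim
from .networks import ArchitectureConfig, build_model
from .objectives import LossWeights
from .training import TrainingConfig, evaluate, fit

__all__ = [
    "SearchSpace",
    "Trial",
    "bayesian_optimize",
    "random_search",
    "grid_search",
    "hpo_objective",
    "default_architecture_space",
]


@dataclass(frozen=True)
class SearchSpace:
    """Finite option lists per hyperparameter; the space is their product."""

    dimensions: dict[str, tuple]

    def __post_init__(self):
        dims = {k: tuple(v) for k, v in self.dimensions.items()}
        object.__setattr__(self, "dimensions", dims)
        if not dims or any(len(v) == 0 for v in dims.values()):
            raise ValueError("every search dimension needs at least one option")

    @property
    def size(self) -> int:
        return math.prod(len(v) for v in self.dimensions.values())

    def contains(self, h: dict) -> bool:
        return set(h) == set(self.dimensions) and all(
            h[k] in v for k, v in self.dimensions.items()
        )

    def sample(self, rng: np.random.Generator) -> dict:
        return {k: v[rng.integers(len(v))] for k, v in self.dimensions.items()}

    def grid(self):
        keys = list(self.dimensions)
        for combo in itertools.product(*(self.dimensions[k] for k in keys)):
            yield dict(zip(keys, combo))


@dataclass
class Trial:
    hyperparameters: dict
    score: float
    status: str = "ok"  # ok | diverged


def _key(h: dict) -> tuple:
    return tuple(sorted((k, repr(v)) for k, v in h.items()))


def _best(history: list[Trial]) -> Trial:
    return min(history, key=lambda t: t.score)


def random_search(
    objective: Callable[[dict], float],
    space: SearchSpace,
    n_iter: int,
    seed: int = 0,
) -> tuple[Trial, list[Trial]]:
    """Uniform i.i.d. draws from the space; duplicate draws reuse cached scores."""
    rng = np.random.default_rng(seed)
    history: list[Trial] = []
    cache: dict[tuple, float] = {}
    for _ in range(n_iter):
        h = space.sample(rng)
        history.append(_evaluate_cached(objective, h, cache))
    return _best(history), history


def grid_search(
    objective: Callable[[dict], float], space: SearchSpace
) -> tuple[Trial, list[Trial]]:
    """Exhaustive evaluation of the whole (finite) space."""
    history = [_evaluate_cached(objective, h, {}) for h in space.grid()]
    return _best(history), history


def _evaluate_cached(objective, h: dict, cache: dict) -> Trial:
    k = _key(h)
    if k in cache:
        score, status = cache[k]
        return Trial(h, score, status)
    try:
        score = float(objective(h))
    except FloatingPointError:
        score = float("inf")
    status = "ok" if math.isfinite(score) else "diverged"
    if not math.isfinite(score):
        score = float("inf")
    cache[k] = (score, status)
    return Trial(h, score, status)


def bayesian_optimize(
    objective: Callable[[dict], float],
    space: SearchSpace,
    n_iter: int = 200,
    gamma: float = 0.25,
    n_candidates: int = 24,
    n_warmup: int = 5,
    seed: int = 0,
) -> tuple[Trial, list[Trial]]:
    """TPE loop over a discrete space.

    After ``n_warmup`` random draws, each iteration splits the completed
    trials at the gamma-quantile of their scores, fits smoothed
    categorical densities l (good side) and g (bad side) per dimension,
    draws ``n_candidates`` from l and evaluates the one with the largest
    density ratio l(h)/g(h).  Returns the incumbent best trial and the
    full history.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    history: list[Trial] = []
    cache: dict[tuple, float] = {}
    n_warmup = min(n_warmup, n_iter)
    for _ in range(n_warmup):
        history.append(_evaluate_cached(objective, space.sample(rng), cache))
    while len(history) < n_iter:
        finished = [t for t in history if t.status == "ok"]
        if len(finished) < 2:
            history.append(_evaluate_cached(objective, space.sample(rng), cache))
            continue
        scores = np.array([t.score for t in finished])
        cut = np.quantile(scores, gamma)
        good = [t for t in finished if t.score <= cut] or finished[:1]
        bad = [t for t in finished if t.score > cut] or finished[-1:]
        l_density = _fit_densities(good, space)
        g_density = _fit_densities(bad, space)
        candidates = [_sample_from(l_density, space, rng) for _ in range(n_candidates)]
        candidates.sort(
            key=lambda h: _log_density(h, l_density) - _log_density(h, g_density),
            reverse=True,
        )
        # prefer the best-ratio candidate not yet evaluated; an already
        # cached point adds no information (its score is merely replayed)
        best_h = next((h for h in candidates if _key(h) not in cache), candidates[0])
        history.append(_evaluate_cached(objective, best_h, cache))
    return _best(history), history


def _fit_densities(trials: list[Trial], space: SearchSpace) -> dict[str, dict]:
    """Per-dimension categorical densities with add-one smoothing."""
    out: dict[str, dict] = {}
    for dim, options in space.dimensions.items():
        counts = {opt: 1.0 for opt in options}  # add-one smoothing
        for t in trials:
            counts[t.hyperparameters[dim]] += 1.0
        total = sum(counts.values())
        out[dim] = {opt: c / total for opt, c in counts.items()}
    return out


def _sample_from(density: dict[str, dict], space: SearchSpace, rng) -> dict:
    h = {}
    for dim, options in space.dimensions.items():
        probs = np.array([density[dim][o] for o in options])
        h[dim] = options[rng.choice(len(options), p=probs / probs.sum())]
    return h


def _log_density(h: dict, density: dict[str, dict]) -> float:
    return float(sum(math.log(density[dim][h[dim]]) for dim in density))


# ---------------------------------------------------------------------------
# the network-training objective


def default_architecture_space(kind: str = "DropoutCAE") -> SearchSpace:
    """Desk-scale architecture search space (one point per trial)."""
    dims = {
        "encoder_units": ((128, 64), (64, 32), (96, 48), (64,)),
        "cic_dim": (8, 12, 16, 20, 32),
        "activation": ("relu", "linear", "softplus"),
        "input_noise_sd": (0.0, 0.01, 0.05, 0.1),
        "batch_size": (50, 100),
    }
    if kind in ("DropoutCAE", "DropoutVAE"):
        dims["dropout_rate"] = (0.0, 0.25, 0.5)
        dims["dropout_kind"] = ("bernoulli", "gaussian")
    return SearchSpace(dims)


def architecture_from_point(kind: str, h: dict) -> ArchitectureConfig:
    """Turn one search-space point into a buildable architecture config."""
    enc = tuple(h["encoder_units"])
    cic = min(h["cic_dim"], min(enc))
    return ArchitectureConfig(
        kind=kind,
        encoder_units=enc,
        decoder_units=tuple(reversed(enc)),
        cic_dim=cic,
        activation=h.get("activation", "softplus"),
        dropout_kind=h.get("dropout_kind", "none") if kind.startswith("Dropout") else "none",
        dropout_rate=h.get("dropout_rate", 0.0) if kind.startswith("Dropout") else 0.0,
        input_noise_sd=h.get("input_noise_sd", 0.0),
        batch_size=h.get("batch_size", 50),
    )


def hpo_objective(
    arch_kind: str,
    dataset: PairedDataset,
    h: dict,
    reduced_epochs: int = 20,
    seed: int = 0,
    weights: LossWeights | None = None,
) -> float:
    """Score one hyperparameter point: train on an 80/20 split and return
    the average total loss over all data.  NaN losses score +inf."""
    arch = architecture_from_point(arch_kind, h)
    split, retained = split_and_trim(
        dataset, test_fraction=0.2, batch_size=arch.batch_size, seed=seed
    )
    train = retained.subset(split.train_indices)
    model = build_model(
        arch,
        n_mrna=dataset.mrna.n_features,
        n_mirna=dataset.mirna.n_features,
        n_tissue=len(dataset.tissue_vocab),
        n_disease=len(dataset.disease_vocab),
        seed=seed,
        tissue_vocab=dataset.tissue_vocab,
        disease_vocab=dataset.disease_vocab,
    )
    cfg = TrainingConfig(epochs=reduced_epochs, weights=weights or LossWeights(), seed=seed)
    model, _ = fit(model, train, None, cfg, record_history=False)
    breakdown, _, _ = evaluate(model, retained, cfg.weights)
    total = breakdown.total
    return float("inf") if not math.isfinite(total) else total
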