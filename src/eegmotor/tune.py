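"""Joint hyperparameter optimisation over the architectures' categorical grids.

Both regressor search spaces are finite products of categorical choices, so
the Tree-structured Parzen Estimator reduces to per-dimension smoothed
categorical densities: past trials are split at a loss quantile, candidate
points are drawn from the "good" density and ranked by the likelihood ratio
l(x)/g(x).  A seeded random-search strategy is the pluggable alternative.

The optimisation objective is validation mean absolute error (FMA points)
from a train-then-validate evaluation of each sampled configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .features import LabeledDataset
from .models import (CNN_BATCH_GRID, CNN_FILTER_GRID, CNN_KERNEL_GRID,
                     DROPOUT_GRID, ITERATION_GRID, RESNET_BATCH_GRID,
                     RESNET_BLOCK_GRID, RESNET_FILTER_GRID,
                     RESNET_KERNEL_GRID, CnnConfig, ResNetConfig, build_model,
                     train_model)


@dataclass
class SearchSpace:
    """Named categorical dimensions for one architecture."""

    arch: str
    dimensions: dict[str, tuple]

    def __post_init__(self):
        if self.arch not in ("cnn", "resnet"):
            raise ValueError("arch must be 'cnn' or 'resnet'")
        self.dimensions = {k: tuple(v) for k, v in self.dimensions.items()}
        for name, values in self.dimensions.items():
            if len(values) == 0:
                raise ValueError(f"dimension {name} is empty")

    def sample(self, rng: np.random.Generator) -> dict:
        return {name: values[rng.integers(len(values))]
                for name, values in self.dimensions.items()}

    def contains(self, point: dict) -> bool:
        return all(point.get(k) in v for k, v in self.dimensions.items())

    def to_config(self, point: dict):
        point = dict(point)
        if self.arch == "resnet" and isinstance(
                point.get("blocks_per_stage"), int):
            b = point["blocks_per_stage"]
            point["blocks_per_stage"] = (b, b, b)
        cls = CnnConfig if self.arch == "cnn" else ResNetConfig
        return cls(**point).validate()

    def to_yaml(self, path):
        doc = {"arch": self.arch,
               "dimensions": {k: [list(v) if isinstance(v, tuple) else v
                                  for v in vals]
                              for k, vals in self.dimensions.items()}}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @staticmethod
    def from_yaml(path) -> "SearchSpace":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        dims = {k: tuple(tuple(v) if isinstance(v, list) else v
                         for v in vals)
                for k, vals in doc["dimensions"].items()}
        return SearchSpace(doc["arch"], dims)


def cnn_search_space() -> SearchSpace:
    return SearchSpace("cnn", {
        "conv1_filters": CNN_FILTER_GRID,
        "conv1_kernel": CNN_KERNEL_GRID,
        "conv2_filters": CNN_FILTER_GRID,
        "dropout_rate": DROPOUT_GRID,
        "batch_size": CNN_BATCH_GRID,
        "iterations": ITERATION_GRID,
    })


def resnet_search_space() -> SearchSpace:
    return SearchSpace("resnet", {
        "blocks_per_stage": RESNET_BLOCK_GRID,
        "stage1_filters": RESNET_FILTER_GRID,
        "block_second_kernel": RESNET_KERNEL_GRID,
        "dropout_rate": DROPOUT_GRID,
        "batch_size": RESNET_BATCH_GRID,
        "iterations": ITERATION_GRID,
    })


class RandomSearch:
    def __init__(self, space: SearchSpace, seed: int):
        self.space = space
        self.rng = np.random.default_rng(seed)

    def propose(self, history) -> dict:
        return self.space.sample(self.rng)


class TPESearch:
    """Categorical TPE: smoothed good/bad densities split at a quantile."""

    def __init__(self, space: SearchSpace, seed: int, gamma: float = 0.25,
                 n_startup: int = 5, n_candidates: int = 24):
        self.space = space
        self.rng = np.random.default_rng(seed)
        self.gamma = gamma
        self.n_startup = n_startup
        self.n_candidates = n_candidates

    def _density(self, points: list[dict], name: str, values: tuple):
        counts = np.ones(len(values))            # +1 smoothing
        lookup = {v: i for i, v in enumerate(values)}
        for p in points:
            counts[lookup[p[name]]] += 1
        return counts / counts.sum()

    def propose(self, history) -> dict:
        if len(history) < self.n_startup:
            return self.space.sample(self.rng)
        ranked = sorted(history, key=lambda h: h[1])
        n_good = max(1, math.ceil(self.gamma * len(ranked)))
        good = [p for p, _ in ranked[:n_good]]
        bad = [p for p, _ in ranked[n_good:]] or good
        best, best_score = None, -np.inf
        densities = {
            name: (self._density(good, name, values),
                   self._density(bad, name, values))
            for name, values in self.space.dimensions.items()}
        for _ in range(self.n_candidates):
            cand, score = {}, 0.0
            for name, values in self.space.dimensions.items():
                l, g = densities[name]
                i = self.rng.choice(len(values), p=l)
                cand[name] = values[i]
                score += np.log(l[i]) - np.log(g[i])
            if score > best_score:
                best, best_score = cand, score
        return best


@dataclass
class TuneResult:
    best_config: object
    best_loss: float
    history: pd.DataFrame        # columns: trial, loss, seed, <dimensions>
    budget: int

    def __post_init__(self):
        if not np.isclose(self.best_loss, self.history["loss"].min()):
            raise ValueError("best loss must equal the history minimum")

    def to_csv(self, path):
        self.history.to_csv(path, index=False)


def _default_objective(space: SearchSpace, train_set: LabeledDataset,
                       val_set: LabeledDataset, learning_rate: float):
    def objective(config, seed):
        trained = train_model(build_model(config), train_set, seed,
                              learning_rate=learning_rate)
        pred = trained.predict(val_set.features)
        return float(np.mean(np.abs(pred - val_set.scores)))
    return objective


def optimize(space: SearchSpace, train_set: LabeledDataset | None,
             val_set: LabeledDataset | None, budget: int,
             strategy: str = "tpe", seed: int = 0, objective=None,
             learning_rate: float = 1e-3) -> TuneResult:
    """Evaluate ``budget`` configurations and return history plus argmin.

    With the default objective each sampled configuration is trained on
    ``train_set`` and scored by MAE on the disjoint ``val_set``.  A custom
    ``objective(config, seed) -> loss`` may replace it (then the data sets
    may be None).
    """
    if budget < 1:
        raise ValueError("budget must be at least 1")
    if objective is None:
        if train_set is None or val_set is None or len(train_set) == 0 \
                or len(val_set) == 0:
            raise ValueError("train and validation sets must be nonempty")
        overlap = set(train_set.trial_ids) & set(val_set.trial_ids)
        if overlap:
            raise ValueError("train and validation trial sets must be "
                             "disjoint")
        objective = _default_objective(space, train_set, val_set,
                                       learning_rate)
    if strategy == "tpe":
        searcher = TPESearch(space, seed)
    elif strategy == "random":
        searcher = RandomSearch(space, seed)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    history: list[tuple[dict, float]] = []
    rows = []
    for trial in range(budget):
        point = searcher.propose(history)
        assert space.contains(point), "sampled point left the search space"
        trial_seed = int(np.random.SeedSequence(
            [int(seed), trial]).generate_state(1)[0] % 2 ** 31)
        loss = float(objective(space.to_config(point), trial_seed))
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite objective for {point}")
        history.append((point, loss))
        rows.append({"trial": trial, "loss": loss, "seed": trial_seed,
                     **{k: str(v) for k, v in point.items()}})
    df = pd.DataFrame(rows)
    best_idx = int(df["loss"].idxmin())
    best_point = history[best_idx][0]
    return TuneResult(space.to_config(best_point),
                      float(df["loss"].min()), df, budget)
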