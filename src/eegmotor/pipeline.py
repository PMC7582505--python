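"""End-to-end orchestration: config-driven runs with manifests and seeds.

A run config (YAML) drives simulate/ingest -> preprocess -> featurize ->
train (or tune) -> evaluate.  One global seed fans out to per-stage seeds
through ``numpy.random.SeedSequence([seed, stage_index])`` so each stage is
individually reproducible, and every run writes a manifest (config hash,
seed, stage counts) next to its artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import evaluate as ev
from . import models, tune
from .io import default_montage, load_montage, store_features
from .preprocess import EpochSpec
from .simulate import SimPoolSpec, simulate_pool

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "features", "train", "tune", "evaluate")


DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "run",
    "montage": None,                       # path or None for the default
    "simulate": {
        "n_healthy": 4,
        "n_stroke": 4,
        "train_trials": 60,
        "test_trials": 15,
        "longitudinal_sessions": 6,
        "longitudinal_trials_per_session": 30,
    },
    "preprocess": {
        "low_hz": 1.0,
        "high_hz": 45.0,
        "min_gap_s": 9.0,
        "window_length_s": 6.0,
        "first_offset_s": -4.0,
        "step_s": 0.2,
        "epochs_per_event": 5,
    },
    "features": {"standardize": False},
    "model": {
        "arch": "cnn",
        "learning_rate": 1e-3,
        "config": {},                      # overrides of the dataclass fields
    },
    "tune": {"enabled": False, "budget": 10, "strategy": "tpe"},
    "evaluate": {"lower_bound": -5.0, "upper_bound": 6.6, "alpha": 0.05},
}


def load_config(path=None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))   # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    return int(np.random.SeedSequence(
        [int(global_seed), STAGES.index(stage)]).generate_state(1)[0]
        % 2 ** 31)


def epoch_spec_from_config(cfg: dict) -> EpochSpec:
    p = cfg["preprocess"]
    return EpochSpec(window_length_s=p["window_length_s"],
                     first_offset_s=p["first_offset_s"], step_s=p["step_s"],
                     epochs_per_event=p["epochs_per_event"],
                     min_event_gap_s=p["min_gap_s"])


def model_config_from_config(cfg: dict):
    arch = cfg["model"]["arch"]
    overrides = {k: (tuple(v) if isinstance(v, list) else v)
                 for k, v in (cfg["model"]["config"] or {}).items()}
    cls = models.CnnConfig if arch == "cnn" else models.ResNetConfig
    return cls(**overrides).validate()


def run_pipeline(cfg: dict) -> dict:
    """Execute every stage; returns the manifest dict (also written to disk)."""
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    montage = (load_montage(cfg["montage"]) if cfg["montage"]
               else default_montage())
    epoch_spec = epoch_spec_from_config(cfg)
    counts: dict[str, object] = {}

    # --- simulate + preprocess + features -------------------------------
    sim_cfg = cfg["simulate"]
    pool_spec = SimPoolSpec(n_healthy=sim_cfg["n_healthy"],
                            n_stroke=sim_cfg["n_stroke"],
                            train_trials=sim_cfg["train_trials"],
                            test_trials=sim_cfg["test_trials"])
    logger.info("simulating pool: %d healthy + %d stroke participants",
                pool_spec.n_healthy, pool_spec.n_stroke)
    train_set, test_set = simulate_pool(pool_spec,
                                        seed=stage_seed(seed, "simulate"),
                                        montage=montage,
                                        epoch_spec=epoch_spec)
    counts["train_trials"] = len(train_set)
    counts["test_trials"] = len(test_set)
    counts["events_dropped_by_screening"] = 0   # generator guarantees gaps
    store_features(train_set.features, train_set.index_frame(),
                   out / "train_features.h5")
    store_features(test_set.features, test_set.index_frame(),
                   out / "test_features.h5")

    # --- train / tune ----------------------------------------------------
    lr = cfg["model"]["learning_rate"]
    if cfg["tune"]["enabled"]:
        space = (tune.cnn_search_space() if cfg["model"]["arch"] == "cnn"
                 else tune.resnet_search_space())
        result = tune.optimize(space, train_set, test_set,
                               budget=cfg["tune"]["budget"],
                               strategy=cfg["tune"]["strategy"],
                               seed=stage_seed(seed, "tune"),
                               learning_rate=lr)
        result.to_csv(out / "tune_history.csv")
        model_config = result.best_config
        counts["tune_trials"] = cfg["tune"]["budget"]
    else:
        model_config = model_config_from_config(cfg)
    trained = models.train_model(models.build_model(model_config), train_set,
                                 seed=stage_seed(seed, "train"),
                                 learning_rate=lr)
    models.save_model(trained, out / "model")
    counts["model_parameters"] = trained.network.n_parameters()
    counts["final_training_loss"] = float(trained.loss_trace[-1])

    # --- evaluate ---------------------------------------------------------
    spec = ev.EquivalenceSpec(lower_bound=cfg["evaluate"]["lower_bound"],
                              upper_bound=cfg["evaluate"]["upper_bound"],
                              alpha=cfg["evaluate"]["alpha"])
    report = ev.within_participant_eval(trained, test_set, spec)
    report.to_json(out / "report.json")
    (out / "report.txt").write_text(report.to_table() + "\n")
    counts["test_mae"] = report.mae
    counts["test_pearson_r"] = report.pearson_r

    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "seed": seed,
        "stage_seeds": {s: stage_seed(seed, s) for s in STAGES},
        "counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
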