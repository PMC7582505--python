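"""CNN and ResNet regressors mapping 270 x 32 x 2 tensors to one FMA score.

The CNN is two convolution/max-pool stages followed by a 100-25-10-5-1
dense head with one dropout layer, ELU activations throughout.  The ResNet
is a convolutional stem, three residual stages (channel count doubling and
resolution halving at each stage transition), global average pooling and a
three-layer dense head with one dropout layer.

Hyperparameters are constrained to fixed categorical grids (see
``CnnConfig``/``ResNetConfig``); training minimises mean squared error with
Adam, is deterministic under a fixed seed, and internally standardises both
input features and targets (statistics are stored with the model and undone
at prediction time).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

from . import nn
from .features import LabeledDataset

INPUT_SHAPE = (270, 32, 2)

CNN_FILTER_GRID = (25, 50, 100)
CNN_KERNEL_GRID = tuple((h, w) for h in (2, 4, 6, 8, 10)
                        for w in (2, 4, 6, 8, 10))
DROPOUT_GRID = tuple(round(0.05 * k, 2) for k in range(21))
CNN_BATCH_GRID = (64, 128)
ITERATION_GRID = (100, 150, 200)

RESNET_BLOCK_GRID = (1, 2, 3)
RESNET_FILTER_GRID = (8, 16, 32)
RESNET_KERNEL_GRID = ((2, 2), (3, 3), (5, 5))
RESNET_BATCH_GRID = (16, 32, 64)


def _check(value, grid, name):
    if value not in grid:
        raise ValueError(f"{name}={value!r} outside the search grid {grid}")


@dataclass(frozen=True)
class CnnConfig:
    conv1_filters: int = 25
    conv1_kernel: tuple[int, int] = (2, 2)
    conv2_filters: int = 25
    conv2_kernel: tuple[int, int] = (2, 2)
    dropout_rate: float = 0.0
    batch_size: int = 64
    iterations: int = 100

    def validate(self):
        _check(self.conv1_filters, CNN_FILTER_GRID, "conv1_filters")
        _check(tuple(self.conv1_kernel), CNN_KERNEL_GRID, "conv1_kernel")
        _check(self.conv2_filters, CNN_FILTER_GRID, "conv2_filters")
        if tuple(self.conv2_kernel) != (2, 2):
            raise ValueError("conv2_kernel is fixed at (2, 2)")
        _check(round(self.dropout_rate, 2), DROPOUT_GRID, "dropout_rate")
        _check(self.batch_size, CNN_BATCH_GRID, "batch_size")
        _check(self.iterations, ITERATION_GRID, "iterations")
        return self


@dataclass(frozen=True)
class ResNetConfig:
    blocks_per_stage: tuple[int, int, int] = (1, 1, 1)
    stage1_filters: int = 16
    block_second_kernel: tuple[int, int] = (3, 3)
    dropout_rate: float = 0.0
    batch_size: int = 32
    iterations: int = 100
    n_stages: int = 3
    fc_layers: int = 3
    dropout_layers: int = 1

    def validate(self):
        if self.n_stages != 3 or self.fc_layers != 3 or self.dropout_layers != 1:
            raise ValueError("structure is fixed: 3 stages, 3 dense layers, "
                             "1 dropout layer")
        if len(self.blocks_per_stage) != 3:
            raise ValueError("blocks_per_stage must have one entry per stage")
        for b in self.blocks_per_stage:
            _check(b, RESNET_BLOCK_GRID, "blocks_per_stage")
        _check(self.stage1_filters, RESNET_FILTER_GRID, "stage1_filters")
        _check(tuple(self.block_second_kernel), RESNET_KERNEL_GRID,
               "block_second_kernel")
        _check(round(self.dropout_rate, 2), DROPOUT_GRID, "dropout_rate")
        _check(self.batch_size, RESNET_BATCH_GRID, "batch_size")
        _check(self.iterations, ITERATION_GRID, "iterations")
        return self


def _cnn_layers(cfg: CnnConfig):
    # ELU is monotone increasing, so ELU-then-maxpool equals
    # maxpool-then-ELU; pooling first applies the transcendental to a
    # quarter of the elements without changing the computed function.
    return [
        nn.Conv2D(cfg.conv1_filters, cfg.conv1_kernel),
        nn.MaxPool2D((2, 2)), nn.ELU(),
        nn.Conv2D(cfg.conv2_filters, cfg.conv2_kernel),
        nn.MaxPool2D((2, 2)), nn.ELU(),
        nn.Flatten(),
        nn.Dense(100), nn.ELU(),
        nn.Dropout(cfg.dropout_rate),
        nn.Dense(25), nn.ELU(),
        nn.Dense(10), nn.ELU(),
        nn.Dense(5), nn.ELU(),
        nn.Dense(1),
    ]


def _resnet_layers(cfg: ResNetConfig):
    f = cfg.stage1_filters
    k2 = cfg.block_second_kernel
    layers = [nn.Conv2D(f, (3, 3), padding="same"), nn.BatchNorm(), nn.ELU()]
    for stage, blocks in enumerate(cfg.blocks_per_stage):
        filters = f * 2 ** stage
        for b in range(blocks):
            stride = 2 if (stage > 0 and b == 0) else 1
            layers.append(nn.ResidualBlock(filters, second_kernel=k2,
                                           stride=stride))
    layers += [
        nn.GlobalAveragePool(),
        nn.Dense(100), nn.ELU(),
        nn.Dropout(cfg.dropout_rate),
        nn.Dense(10), nn.ELU(),
        nn.Dense(1),
    ]
    return layers


@dataclass
class UntrainedModel:
    """A validated architecture plan; weights appear at training time."""

    arch: str
    config: CnnConfig | ResNetConfig
    input_shape: tuple = INPUT_SHAPE

    def instantiate(self, seed: int) -> nn.Network:
        factory = _cnn_layers if self.arch == "cnn" else _resnet_layers
        return nn.Network(factory(self.config), self.input_shape, seed)

    def n_parameters(self) -> int:
        return self.instantiate(0).n_parameters()


def build_model(config: CnnConfig | ResNetConfig,
                input_shape=INPUT_SHAPE) -> UntrainedModel:
    if isinstance(config, CnnConfig):
        arch = "cnn"
    elif isinstance(config, ResNetConfig):
        arch = "resnet"
    else:
        raise TypeError("config must be a CnnConfig or ResNetConfig")
    config.validate()
    model = UntrainedModel(arch, config, tuple(input_shape))
    model.instantiate(0)     # fail fast on shape-incompatible configs
    return model


@dataclass
class TrainedModel:
    arch: str
    config: CnnConfig | ResNetConfig
    network: nn.Network
    seed: int
    loss_trace: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float

    def predict(self, tensors: np.ndarray, clip: bool = False,
                chunk: int = 256) -> np.ndarray:
        """One real-valued score per trial; unbounded unless ``clip``."""
        x = np.asarray(tensors, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != tuple(self.network.input_shape):
            raise ValueError(
                f"tensors have shape {x.shape[1:]}, model expects "
                f"{self.network.input_shape}")
        out = []
        for start in range(0, len(x), chunk):
            xb = (x[start:start + chunk] - self.x_mean) / self.x_std
            out.append(self.network.forward(xb, training=False)[:, 0])
        scores = np.concatenate(out) * self.y_std + self.y_mean
        if clip:
            scores = np.clip(scores, 0.0, 66.0)
        return scores


def train_model(model: UntrainedModel, dataset: LabeledDataset, seed: int,
                learning_rate: float = 1e-3, max_restarts: int = 3,
                collapse_steps: int = 80, collapse_threshold: float = 0.5
                ) -> TrainedModel:
    """Fit the regressor by minibatch MSE/Adam for ``iterations`` epochs.

    Inputs are standardised per plane (one scalar mean/std over all power
    entries, one over all phase entries, computed on the training set): the
    spectral tensors are naturally sparse — rhythm bins carry orders of
    magnitude more power than background bins — and that concentration is
    what the convolutional front end keys on.  Per-feature z-scoring would
    inflate thousands of background bins to unit variance and drown the
    signal.  Targets are z-scored; all statistics are stored on the model
    and inverted at prediction time.  Training is deterministic given the
    seed.

    A minority of weight initialisations fall into the saturated
    constant-output basin (the network then only ever predicts the label
    mean).  Training probes for this after ``collapse_steps`` gradient
    steps — on z-scored targets a mean predictor has MSE 1, a learning run
    is well below ``collapse_threshold`` by then — and restarts from a
    deterministically derived seed, up to ``max_restarts`` times.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    y = np.asarray(dataset.scores, dtype=float)
    if y.min() < 0 or y.max() > 66:
        raise ValueError("labels must lie in [0, 66]")
    x = np.asarray(dataset.features, dtype=np.float32)
    x_mean = x.mean(axis=(0, 1, 2))                      # one scalar per plane
    x_std = np.maximum(x.std(axis=(0, 1, 2)), 1e-6).astype(np.float32)
    y_mean = float(y.mean())
    y_std = float(max(y.std(), 1e-6))
    xs = (x - x_mean) / x_std
    ys = (y - y_mean) / y_std

    cfg = model.config
    steps_per_epoch = max(1, int(np.ceil(len(xs) / cfg.batch_size)))
    probe = int(np.ceil(collapse_steps / steps_per_epoch))
    if probe >= cfg.iterations or np.std(ys) == 0:
        probe = None
    trace = None
    for attempt in range(max_restarts + 1):
        attempt_seed = int(seed) if attempt == 0 else int(
            np.random.SeedSequence([int(seed), attempt])
            .generate_state(1)[0] % 2 ** 31)
        net = model.instantiate(attempt_seed)
        try:
            trace = nn.fit_mse(
                net, xs, ys, epochs=cfg.iterations,
                batch_size=cfg.batch_size, lr=learning_rate,
                seed=attempt_seed,
                collapse_epoch=probe if attempt < max_restarts else None,
                collapse_threshold=collapse_threshold)
        except FloatingPointError as err:
            raise FloatingPointError(
                f"{err} (arch={model.arch}, config={cfg})") from err
        if len(trace) == cfg.iterations:
            break
        logger.warning(
            "training collapsed to the constant predictor (loss %.3f after "
            "%d epochs); restarting from derived seed (attempt %d)",
            trace[-1], len(trace), attempt + 1)
    return TrainedModel(model.arch, cfg, net, int(seed), trace,
                        x_mean.astype(np.float32), x_std, y_mean, y_std)


def predict_scores(trained: TrainedModel, tensors: np.ndarray,
                   clip: bool = False) -> np.ndarray:
    return trained.predict(tensors, clip=clip)


# ---------------------------------------------------------------------------
# persistence: npz weights + JSON sidecar
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path_prefix):
    path_prefix = Path(path_prefix)
    weights = model.network.get_weights()
    np.savez(path_prefix.with_suffix(".npz"),
             x_mean=model.x_mean, x_std=model.x_std,
             loss_trace=model.loss_trace,
             **{f"w{i}": w for i, w in enumerate(weights)})
    sidecar = {
        "arch": model.arch,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(model.config).items()},
        "seed": model.seed,
        "input_shape": list(model.network.input_shape),
        "network_seed": model.network.seed,
        "y_mean": model.y_mean,
        "y_std": model.y_std,
        "n_weights": len(weights),
    }
    path_prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def _config_from_dict(arch: str, d: dict):
    cls = CnnConfig if arch == "cnn" else ResNetConfig
    kwargs = {}
    for k, v in d.items():
        if isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)


def load_model(path_prefix) -> TrainedModel:
    path_prefix = Path(path_prefix)
    sidecar = json.loads(path_prefix.with_suffix(".json").read_text())
    config = _config_from_dict(sidecar["arch"], sidecar["config"])
    untrained = UntrainedModel(sidecar["arch"], config,
                               tuple(sidecar["input_shape"]))
    net = untrained.instantiate(sidecar["network_seed"])
    with np.load(path_prefix.with_suffix(".npz")) as z:
        net.set_weights([z[f"w{i}"] for i in range(sidecar["n_weights"])])
        x_mean, x_std = z["x_mean"], z["x_std"]
        trace = z["loss_trace"]
    return TrainedModel(sidecar["arch"], config, net, sidecar["seed"], trace,
                        x_mean, x_std, sidecar["y_mean"], sidecar["y_std"])
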