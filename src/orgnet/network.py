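"""The two 3D-CNN architectures for ΔΔG prediction.

* ``orgnet`` — input conv (16 ch, k=3, p=1) → ReLU → maxpool(k=3, p=1, s=2);
  two blocks of conv (80 then 400 ch, k=3, p=1) → ReLU → maxpool(k=3, p=1,
  s=2); output conv (512 ch, k=2, no padding) → ReLU; then dense 512 → GELU →
  dense 128 → GELU → scalar.  Convolutions carry no additive bias (this is
  what makes the trainable-parameter count come out at exactly 2 871 457 for
  14 input channels); dense layers are biased.  Spatial trace on a 16³ input:
  16³ → 8³ → 4³ → 2³ → 1³.

* ``thermonet_like`` — three valid-padding convolutions (16, 24, 32 ch, k=3,
  all biased) with ReLU, one maxpool (k=2, s=2), then dense 24 → ReLU →
  scalar: 133 273 parameters for 14 input channels.  Spatial trace:
  16 → 14 → 12 → 10 → 5.

Model input is the (16, 16, 16, C) channel-last representation tensor;
channel-first conversion is internal.  In classification mode the scalar
output is squashed through a logistic to a probability of the mutation being
stabilizing (ΔΔG < 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .featurize import GRID_SIZE, Representation
from .nnops import GELU, Conv3d, Flatten, Linear, MaxPool3d, ReLU, Sequential

__all__ = [
    "ModelConfig",
    "Model",
    "build_orgnet",
    "build_thermonet_like",
    "build_model",
    "count_parameters",
    "predict",
    "ensemble_predict",
    "save_checkpoint",
    "load_checkpoint",
]

ARCHITECTURES = ("orgnet", "thermonet_like")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture choice, input channel count, and output head."""

    architecture: str = "orgnet"
    in_channels: int = 14
    head: str = "regression"

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")
        if self.head not in ("regression", "classification"):
            raise ValueError("head must be 'regression' or 'classification'")


@dataclass
class Model:
    """A built network with its configuration and initialization seed."""

    net: Sequential
    config: ModelConfig
    seed: int = 0

    def n_parameters(self) -> int:
        return self.net.n_parameters()


def build_orgnet(config: ModelConfig, seed: int = 0) -> Model:
    """Build the deeper architecture (2 871 457 parameters at 14 channels)."""
    if config.architecture != "orgnet":
        raise ValueError("config.architecture must be 'orgnet'")
    if config.in_channels not in (7, 14):
        raise ValueError("in_channels must be 7 or 14")
    rng = np.random.default_rng(seed)
    layers = [
        Conv3d(config.in_channels, 16, kernel=3, padding=1, bias=False, rng=rng),
        ReLU(),
        MaxPool3d(kernel=3, stride=2, padding=1),
        Conv3d(16, 80, kernel=3, padding=1, bias=False, rng=rng),
        ReLU(),
        MaxPool3d(kernel=3, stride=2, padding=1),
        Conv3d(80, 400, kernel=3, padding=1, bias=False, rng=rng),
        ReLU(),
        MaxPool3d(kernel=3, stride=2, padding=1),
        Conv3d(400, 512, kernel=2, padding=0, bias=False, rng=rng),
        ReLU(),
        Flatten(),
        Linear(512, 512, rng=rng),
        GELU(),
        Linear(512, 128, rng=rng),
        GELU(),
        Linear(128, 1, rng=rng),
    ]
    return Model(net=Sequential(layers), config=config, seed=seed)


def build_thermonet_like(config: ModelConfig, seed: int = 0) -> Model:
    """Build the compact reference architecture (133 273 parameters)."""
    if config.architecture != "thermonet_like":
        raise ValueError("config.architecture must be 'thermonet_like'")
    if config.in_channels != 14:
        raise ValueError("the compact architecture takes 14 input channels")
    rng = np.random.default_rng(seed)
    layers = [
        Conv3d(14, 16, kernel=3, rng=rng),
        ReLU(),
        Conv3d(16, 24, kernel=3, rng=rng),
        ReLU(),
        Conv3d(24, 32, kernel=3, rng=rng),
        ReLU(),
        MaxPool3d(kernel=2, stride=2),
        Flatten(),
        Linear(5**3 * 32, 24, rng=rng),
        ReLU(),
        Linear(24, 1, rng=rng),
    ]
    return Model(net=Sequential(layers), config=config, seed=seed)


def build_model(config: ModelConfig, seed: int = 0) -> Model:
    if config.architecture == "orgnet":
        return build_orgnet(config, seed)
    return build_thermonet_like(config, seed)


def count_parameters(model: Model) -> int:
    """Total number of trainable scalar parameters."""
    return model.n_parameters()


def _as_batch(model: Model, representation) -> np.ndarray:
    if isinstance(representation, Representation):
        x = representation.tensor[None]
    else:
        x = np.asarray(representation, dtype=float)
        if x.ndim == 4:
            x = x[None]
    expected = (GRID_SIZE,) * 3 + (model.config.in_channels,)
    if x.shape[1:] != expected:
        raise ValueError(f"expected input of shape {expected}, got {x.shape[1:]}")
    return x.transpose(0, 4, 1, 2, 3)  # channel-first


def predict(model: Model, representation) -> np.ndarray | float:
    """Deterministic forward pass; probability in [0,1] for classification.

    Accepts a Representation, a (16,16,16,C) tensor, or a batch of them;
    returns a scalar for single inputs, an array for batches.
    """
    x = _as_batch(model, representation)
    out = model.net.forward(x).reshape(-1)
    if model.config.head == "classification":
        out = 1.0 / (1.0 + np.exp(-out))
    if out.shape[0] == 1 and (
        isinstance(representation, Representation)
        or np.asarray(representation).ndim == 4
    ):
        return float(out[0])
    return out


def ensemble_predict(models: list[Model], representation) -> np.ndarray | float:
    """Arithmetic mean of the member predictions."""
    if not models:
        raise ValueError("ensemble needs at least one model")
    cfg = models[0].config
    if any(m.config != cfg for m in models):
        raise ValueError("ensemble members must share a configuration")
    preds = [predict(m, representation) for m in models]
    return float(np.mean(preds)) if np.isscalar(preds[0]) else np.mean(preds, axis=0)


def save_checkpoint(model: Model, path: str | Path) -> None:
    """Save weights (npz) with a JSON sidecar recording config and seed."""
    path = Path(path)
    state = model.net.get_state()
    np.savez(path, **{f"p{i}": p for i, p in enumerate(state)})
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "architecture": model.config.architecture,
                "in_channels": model.config.in_channels,
                "head": model.config.head,
                "seed": model.seed,
            },
            indent=2,
        )
    )


def load_checkpoint(path: str | Path) -> Model:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    config = ModelConfig(
        architecture=meta["architecture"],
        in_channels=meta["in_channels"],
        head=meta["head"],
    )
    model = build_model(config, seed=meta.get("seed", 0))
    with np.load(path if path.suffix == ".npz" else str(path)) as data:
        state = [data[f"p{i}"] for i in range(len(data.files))]
    model.net.set_state(state)
    return model
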