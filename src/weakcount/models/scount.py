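"""S-Count: fully supervised count regression.

A convolutional backbone is followed by a 1×1 convolution producing *N*
response maps (batch-normalized, ReLU) whose flattened activations feed
a linear layer regressing the count. Training minimizes mean squared
error against the integer counts derived from point labels. The raw
regression output is left unclamped during training (clamping would bias
gradients near zero); predictions are clamped at zero and rounded.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from ..nn.layers import BatchNorm2d, Conv2d, Linear, ReLU, Sequential
from ..nn.optim import make_optimizer
from .backbones import build_backbone
from .common import (
    CountPrediction,
    TrainingExample,
    load_params,
    resize_batch,
    save_params,
    to_batch,
)

__all__ = ["SCountConfig", "SCountModel", "build_scount", "mse_loss", "train_scount"]


@dataclass(frozen=True)
class SCountConfig:
    backbone: str = "tiny_cnn"
    n_response_maps: int = 6  # N = 6 response maps is the best-performing default
    input_size_px: int = 64
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    epochs: int = 15
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_response_maps < 1:
            raise ValueError("n_response_maps must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class SCountModel:
    """Backbone → N response maps → fully connected count regressor."""

    def __init__(self, config: SCountConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.trunk, cout, stride = build_backbone(config.backbone, rng)
        if config.input_size_px % stride:
            raise ValueError(
                f"input_size_px must be a multiple of the backbone stride {stride}"
            )
        side = config.input_size_px // stride
        self.head = Sequential(
            Conv2d(cout, config.n_response_maps, 1, rng),
            BatchNorm2d(config.n_response_maps),
            ReLU(),
        )
        self.fc = Linear(config.n_response_maps * side * side, 1, rng)
        self._maps_shape = (config.n_response_maps, side, side)

    # --- engine plumbing -------------------------------------------------
    def params(self):
        return self.trunk.params() + self.head.params() + self.fc.params()

    def state(self):
        out = {f"trunk.{k}": v for k, v in self.trunk.state().items()}
        out.update({f"head.{k}": v for k, v in self.head.state().items()})
        return out

    def forward(
        self, batch: np.ndarray, train: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        """Returns (raw counts (N,), response maps (N, C, h, w))."""
        feats = self.trunk.forward(batch, train=train)
        maps = self.head.forward(feats, train=train)
        self._maps = maps
        flat = maps.reshape(maps.shape[0], -1)
        out = self.fc.forward(flat, train=train)
        return out[:, 0], maps

    def backward(self, dcounts: np.ndarray) -> None:
        dflat = self.fc.backward(dcounts[:, None])
        dmaps = dflat.reshape(self._maps.shape)
        dfeats = self.head.backward(dmaps)
        self.trunk.backward(dfeats)

    # --- user API --------------------------------------------------------
    def predict(self, tile: np.ndarray) -> CountPrediction:
        """Count for one H×W×3 tile (resized to the model's input side)."""
        batch = resize_batch(to_batch([tile]), self.config.input_size_px)
        raw, maps = self.forward(batch, train=False)
        return CountPrediction(count_real=float(raw[0]), response_maps=maps[0])

    def predict_batch(self, tiles) -> list[CountPrediction]:
        batch = resize_batch(to_batch(tiles), self.config.input_size_px)
        raw, _ = self.forward(batch, train=False)
        return [CountPrediction(count_real=float(r)) for r in raw]

    def save(self, path) -> None:
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        arrays.update({f"state.{k}": v for k, v in self.state().items()})
        save_params(path, arrays, {"kind": "scount", "config": asdict(self.config)})

    @classmethod
    def load(cls, path) -> "SCountModel":
        arrays, meta = load_params(path)
        model = cls(SCountConfig(**meta["config"]))
        for i, p in enumerate(model.params()):
            p.value[...] = arrays[f"param_{i}"]
        for k, v in model.state().items():
            v[...] = arrays[f"state.{k}"]
        return model


def build_scount(config: SCountConfig) -> SCountModel:
    """Construct a seeded S-Count model (same config ⇒ same weights)."""
    return SCountModel(config)


def mse_loss(predicted, target) -> float:
    """Mean squared error between two equal-length sequences."""
    p = np.asarray(predicted, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise ValueError("mse_loss needs at least one element")
    return float(np.mean((p - t) ** 2))


def train_scount(
    model: SCountModel,
    examples: list[TrainingExample],
    config: SCountConfig | None = None,
    discard_above: int = 15,
) -> tuple[SCountModel, list[float]]:
    """Train on (tile, count) supervision; returns (model, per-epoch loss).

    Tiles beyond the countable range (count > ``discard_above``) must be
    filtered out by the caller; passing one is an error.
    """
    cfg = config or model.config
    if not examples:
        raise ValueError("empty training dataset")
    targets = np.array([ex.count for ex in examples], dtype=np.float32)
    if (targets > discard_above).any():
        raise ValueError(
            f"dataset contains tiles beyond the countable range (> {discard_above}); "
            "exclude dnc tiles before training"
        )
    batch_all = resize_batch(to_batch([ex.image for ex in examples]), cfg.input_size_px)

    rng = np.random.default_rng(cfg.seed + 1)
    opt = make_optimizer(cfg.optimizer, model.params(), cfg.learning_rate)
    trace = []
    n = len(examples)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, tb = batch_all[idx], targets[idx]
            opt.zero_grad()
            raw, _ = model.forward(xb, train=True)
            diff = raw - tb
            losses.append(float(np.mean(diff**2)))
            model.backward((2.0 * diff / len(idx)).astype(np.float32))
            opt.step()
        trace.append(float(np.mean(losses)))
    return model, trace
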