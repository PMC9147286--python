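"""WS-Count: weakly supervised counting from presence/absence labels only.

Two sub-networks: a presence-absence classifier (PAC) trained with binary
class labels, and a count regressor. A tile is processed at three scales
— the whole tile, its 2×2 quarters and its 4×4 sixteenths, 21 patches in
all — and every patch passes through both networks (shared weights across
branches). The counter never sees a ground-truth count; it is supervised
only by the PAC through two losses:

* classifier consistency ``L_PAC-C``: a patch the PAC calls empty should
  get count 0, a patch the PAC calls occupied should get count ≥ 1
  (margin configurable)::

      L_PAC-C = (1/21) Σ_b [ (1 − p_b)·|c_b| + p_b·max(0, margin − c_b) ]

* spatial consistency ``L_SP-C``: the total count should agree across the
  three scales (C1 = whole-tile count, C4 = sum over quarters, C16 = sum
  over sixteenths)::

      L_SP-C = |C1 − C4| + |C1 − C16| + |C4 − C16|

The optimized objective is exactly their sum. Training is two-stage: the
PAC is fitted first and frozen (optionally fine-tuned) while the counter
minimizes the combined loss.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from ..annotations import ClassLabel
from ..nn.layers import GlobalAvgPool2d, Linear, Sequential, sigmoid
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
from .scount import SCountConfig, SCountModel

__all__ = [
    "MultiScalePatches",
    "BranchOutputs",
    "WSCountLoss",
    "WSCountConfig",
    "PACModel",
    "WSCountModel",
    "split_multiscale",
    "loss_pac_consistency",
    "loss_spatial_consistency",
    "build_wscount",
    "train_pac",
    "train_wscount",
    "predict_wscount",
    "pac_accuracy",
]

N_BRANCHES = 21  # 1 full + 4 quarters + 16 sixteenths


@dataclass
class MultiScalePatches:
    """The 21 patches of a tile in fixed row-major order per scale."""

    full: list[np.ndarray]
    quarters: list[np.ndarray]
    sixteenths: list[np.ndarray]

    @property
    def patches(self) -> list[np.ndarray]:
        return self.full + self.quarters + self.sixteenths


def split_multiscale(tile: np.ndarray) -> MultiScalePatches:
    """Split a square tile into 1 + 4 + 16 even patches (side % 4 == 0)."""
    tile = np.asarray(tile)
    h, w = tile.shape[:2]
    if h != w:
        raise ValueError(f"tile must be square, got {h}×{w}")
    if h % 4:
        raise ValueError(f"tile side {h} not divisible by 4")
    half, quart = h // 2, h // 4
    quarters = [
        tile[r * half : (r + 1) * half, c * half : (c + 1) * half]
        for r in range(2)
        for c in range(2)
    ]
    sixteenths = [
        tile[r * quart : (r + 1) * quart, c * quart : (c + 1) * quart]
        for r in range(4)
        for c in range(4)
    ]
    return MultiScalePatches(full=[tile], quarters=quarters, sixteenths=sixteenths)


@dataclass
class BranchOutputs:
    """Per-branch counts and presence probabilities (length 21 each)."""

    counts: np.ndarray
    presence_probs: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.presence_probs = np.asarray(self.presence_probs, dtype=np.float64)
        if self.counts.shape != (N_BRANCHES,) or self.presence_probs.shape != (
            N_BRANCHES,
        ):
            raise ValueError(f"expected {N_BRANCHES} branch outputs")
        if (self.counts < 0).any():
            raise ValueError("branch counts must be nonnegative")


@dataclass(frozen=True)
class WSCountLoss:
    l_pac_c: float
    l_sp_c: float

    @property
    def total(self) -> float:
        return self.l_pac_c + self.l_sp_c


def _pac_consistency(counts: np.ndarray, probs: np.ndarray, margin: float) -> float:
    return float(
        np.mean((1.0 - probs) * np.abs(counts) + probs * np.maximum(0.0, margin - counts))
    )


def _scale_sums(counts: np.ndarray) -> tuple[float, float, float]:
    return float(counts[0]), float(counts[1:5].sum()), float(counts[5:21].sum())


def loss_pac_consistency(outputs: BranchOutputs, margin: float = 1.0) -> float:
    """Classifier-consistency loss; zero iff every branch agrees with its
    PAC call (p=0 with c=0, or p=1 with c ≥ margin)."""
    probs = np.asarray(outputs.presence_probs, dtype=np.float64)
    if (probs < 0).any() or (probs > 1).any():
        raise ValueError("presence probabilities must lie in [0, 1]")
    return _pac_consistency(np.asarray(outputs.counts, dtype=np.float64), probs, margin)


def loss_spatial_consistency(outputs: BranchOutputs) -> float:
    """Pairwise absolute disagreement of the three per-scale totals."""
    c1, c4, c16 = _scale_sums(np.asarray(outputs.counts, dtype=np.float64))
    return abs(c1 - c4) + abs(c1 - c16) + abs(c4 - c16)


@dataclass(frozen=True)
class WSCountConfig:
    backbone: str = "tiny_cnn"
    n_response_maps: int = 6  # N = 6 feature maps for PAC and counter
    patch_input_px: int = 16  # all 21 patches are resized to this side
    learning_rate: float = 1e-4  # Adam default for the full-scale setting
    optimizer: str = "adam"
    pac_epochs: int = 10
    count_epochs: int = 15
    batch_size: int = 8
    margin: float = 1.0
    prediction: str = "scale1"  # or "scale_mean"
    finetune_pac: bool = False
    pac_crop_augment: bool = True  # train PAC on crops of absent tiles too
    seed: int = 0


class PACModel:
    """Presence-absence classifier: backbone → global pool → logit."""

    def __init__(self, backbone: str, input_px: int, seed: int) -> None:
        rng = np.random.default_rng(seed)
        self.trunk, cout, _ = build_backbone(backbone, rng)
        self.pool = GlobalAvgPool2d()
        self.fc = Linear(cout, 1, rng)
        self.input_px = input_px

    def params(self):
        return self.trunk.params() + self.fc.params()

    def state(self):
        return {f"trunk.{k}": v for k, v in self.trunk.state().items()}

    def forward_logits(self, batch: np.ndarray, train: bool = False) -> np.ndarray:
        feats = self.trunk.forward(batch, train=train)
        pooled = self.pool.forward(feats, train=train)
        return self.fc.forward(pooled, train=train)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        dpooled = self.fc.backward(dlogits[:, None])
        dfeats = self.pool.backward(dpooled)
        self.trunk.backward(dfeats)

    def forward(self, patch: np.ndarray) -> float:
        """Presence probability in [0, 1] for one H×W×3 patch."""
        batch = resize_batch(to_batch([patch]), self.input_px)
        return float(sigmoid(self.forward_logits(batch, train=False))[0])

    def forward_batch(self, batch_nchw: np.ndarray) -> np.ndarray:
        return np.asarray(sigmoid(self.forward_logits(batch_nchw, train=False)))


def pac_forward(model: PACModel, patch: np.ndarray) -> float:
    return model.forward(patch)


class WSCountModel:
    """Shared PAC + shared counter applied to all 21 branches."""

    def __init__(self, config: WSCountConfig) -> None:
        self.config = config
        self.pac = PACModel(config.backbone, config.patch_input_px, config.seed)
        self.counter = SCountModel(
            SCountConfig(
                backbone=config.backbone,
                n_response_maps=config.n_response_maps,
                input_size_px=config.patch_input_px,
                seed=config.seed + 1,
            )
        )

    def params(self):
        return self.pac.params() + self.counter.params()

    def _patch_batch(self, tiles) -> np.ndarray:
        """(B·21, 3, s, s) patch batch in branch-major order per tile."""
        side = self.config.patch_input_px
        batch = to_batch(tiles)  # (B, 3, S, S)
        n, _, h, w = batch.shape
        if h != w or h % 4:
            raise ValueError(f"tiles must be square with side divisible by 4, got {h}×{w}")
        half, quart = h // 2, h // 4
        scales = [resize_batch(batch, side)]  # full
        for r in range(2):  # quarters, row-major
            for c in range(2):
                scales.append(
                    resize_batch(
                        batch[:, :, r * half : (r + 1) * half, c * half : (c + 1) * half],
                        side,
                    )
                )
        for r in range(4):  # sixteenths, row-major
            for c in range(4):
                scales.append(
                    resize_batch(
                        batch[:, :, r * quart : (r + 1) * quart, c * quart : (c + 1) * quart],
                        side,
                    )
                )
        stacked = np.stack(scales, axis=1)  # (B, 21, 3, s, s)
        return np.ascontiguousarray(stacked.reshape(n * N_BRANCHES, 3, side, side))

    def forward_branches(self, tile: np.ndarray) -> BranchOutputs:
        """Evaluation-mode branch outputs (counts clipped at zero)."""
        batch = self._patch_batch([tile])
        raw, _ = self.counter.forward(batch, train=False)
        probs = self.pac.forward_batch(batch)
        return BranchOutputs(
            counts=np.maximum(raw.astype(np.float64), 0.0),
            presence_probs=np.clip(probs, 0.0, 1.0),
        )

    def loss(self, tile: np.ndarray) -> WSCountLoss:
        out = self.forward_branches(tile)
        return WSCountLoss(
            l_pac_c=loss_pac_consistency(out, self.config.margin),
            l_sp_c=loss_spatial_consistency(out),
        )

    def predict(self, tile: np.ndarray) -> CountPrediction:
        out = self.forward_branches(tile)
        if self.config.prediction == "scale_mean":
            c1, c4, c16 = _scale_sums(out.counts)
            value = (c1 + c4 + c16) / 3.0
        else:
            value = float(out.counts[0])
        return CountPrediction(count_real=value)

    def save(self, path) -> None:
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        arrays.update({f"pac.{k}": v for k, v in self.pac.state().items()})
        arrays.update({f"cnt.{k}": v for k, v in self.counter.state().items()})
        save_params(path, arrays, {"kind": "wscount", "config": asdict(self.config)})

    @classmethod
    def load(cls, path) -> "WSCountModel":
        arrays, meta = load_params(path)
        model = cls(WSCountConfig(**meta["config"]))
        for i, p in enumerate(model.params()):
            p.value[...] = arrays[f"param_{i}"]
        for k, v in model.pac.state().items():
            v[...] = arrays[f"pac.{k}"]
        for k, v in model.counter.state().items():
            v[...] = arrays[f"cnt.{k}"]
        return model


def build_wscount(config: WSCountConfig) -> WSCountModel:
    return WSCountModel(config)


def _coerce_weak_examples(dataset) -> list[TrainingExample]:
    """Accept TrainingExamples or (tile, class_label) pairs.

    Passing count supervision (numeric labels) to the weak trainer is an
    error: WS-Count's contract is that it never consumes counts.
    """
    examples = []
    for item in dataset:
        if isinstance(item, TrainingExample):
            examples.append(item)
            continue
        tile, label = item
        if isinstance(label, bool):
            label = ClassLabel.PRESENT if label else ClassLabel.ABSENT
        elif isinstance(label, str):
            label = ClassLabel(label)
        elif isinstance(label, ClassLabel):
            pass
        else:
            raise TypeError(
                f"weak trainer got label {label!r}: WS-Count consumes only "
                "presence/absence labels, never counts"
            )
        examples.append(TrainingExample(image_=tile, class_label_=label))
    return examples


def train_pac(
    model: WSCountModel | PACModel,
    dataset,
    config: WSCountConfig | None = None,
) -> list[float]:
    """Stage 1: fit the presence-absence classifier with class labels.

    Returns the per-epoch binary cross-entropy trace.
    """
    pac = model.pac if isinstance(model, WSCountModel) else model
    cfg = config or (model.config if isinstance(model, WSCountModel) else WSCountConfig())
    examples = _coerce_weak_examples(dataset)
    if not examples:
        raise ValueError("empty training dataset")
    labels = [1.0 if ex.class_label is ClassLabel.PRESENT else 0.0 for ex in examples]
    batches = [resize_batch(to_batch([ex.image for ex in examples]), cfg.patch_input_px)]
    if cfg.pac_crop_augment:
        # A crop of an absent tile is certainly absent, so sub-patches of
        # absent tiles are label-safe extra negatives. They teach the PAC
        # what magnified background looks like — exactly what it sees on
        # the quarter/sixteenth branches at counting time.
        for ex, label in zip(list(examples), list(labels)):
            if label == 1.0:
                continue
            for patch in split_multiscale(ex.image).patches[1:]:
                batches.append(resize_batch(to_batch([patch]), cfg.patch_input_px))
                labels.append(0.0)
    batch_all = np.concatenate(batches, axis=0)
    labels = np.array(labels, dtype=np.float32)
    rng = np.random.default_rng(cfg.seed + 11)
    opt = make_optimizer(cfg.optimizer, pac.params(), cfg.learning_rate)
    trace = []
    n = len(examples)
    for _epoch in range(cfg.pac_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, max(cfg.batch_size, 16)):
            idx = order[start : start + max(cfg.batch_size, 16)]
            xb, yb = batch_all[idx], labels[idx]
            opt.zero_grad()
            logits = pac.forward_logits(xb, train=True)
            p = np.asarray(sigmoid(logits))
            eps = 1e-12
            losses.append(
                float(-np.mean(yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps)))
            )
            pac.backward(((p - yb) / len(idx)).astype(np.float32))
            opt.step()
        trace.append(float(np.mean(losses)))
    return trace


def train_wscount(
    model: WSCountModel,
    dataset,
    config: WSCountConfig | None = None,
    stages: tuple[str, ...] = ("pac", "count"),
) -> tuple[WSCountModel, list[WSCountLoss]]:
    """Two-stage weakly supervised training on class labels only.

    Stage ``"pac"`` fits the classifier; stage ``"count"`` freezes it
    (unless ``finetune_pac``) and trains the counter to minimize
    ``L_PAC-C + L_SP-C``. Returns (model, per-epoch loss trace of the
    counting stage).
    """
    cfg = config or model.config
    examples = _coerce_weak_examples(dataset)
    if not examples:
        raise ValueError("empty training dataset")

    if "pac" in stages:
        train_pac(model, examples, cfg)
    trace: list[WSCountLoss] = []
    if "count" not in stages:
        return model, trace

    patch_all = model._patch_batch([ex.image for ex in examples])  # (n*21, 3, s, s)
    n = len(examples)
    rng = np.random.default_rng(cfg.seed + 23)
    opt = make_optimizer(cfg.optimizer, model.counter.params(), cfg.learning_rate)
    pac_opt = (
        make_optimizer(cfg.optimizer, model.pac.params(), cfg.learning_rate)
        if cfg.finetune_pac
        else None
    )
    for _epoch in range(cfg.count_epochs):
        order = rng.permutation(n)
        pac_losses, sp_losses = [], []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            b = len(idx)
            rows = (idx[:, None] * N_BRANCHES + np.arange(N_BRANCHES)).ravel()
            xb = patch_all[rows]
            probs = model.pac.forward_batch(xb).reshape(b, N_BRANCHES)
            opt.zero_grad()
            raw, _ = model.counter.forward(xb, train=True)
            c = raw.reshape(b, N_BRANCHES).astype(np.float64)

            # L_PAC-C and its subgradient wrt each branch count
            m = cfg.margin
            pac_losses.append(
                float(
                    np.mean(
                        np.mean(
                            (1 - probs) * np.abs(c)
                            + probs * np.maximum(0.0, m - c),
                            axis=1,
                        )
                    )
                )
            )
            dc = ((1 - probs) * np.sign(c) - probs * (c < m)) / N_BRANCHES

            # L_SP-C and its subgradient via the three scale totals
            c1 = c[:, 0]
            c4 = c[:, 1:5].sum(axis=1)
            c16 = c[:, 5:21].sum(axis=1)
            sp_losses.append(
                float(np.mean(np.abs(c1 - c4) + np.abs(c1 - c16) + np.abs(c4 - c16)))
            )
            # Huber-smoothed subgradients (sign → clipped difference, knee
            # at 1 boll): near scale consensus the raw sign subgradients
            # flip every step and their noise swamps the 1/21-scaled
            # classifier-consistency signal, pinning training at the
            # degenerate all-zero consensus
            s14 = np.clip(c1 - c4, -1.0, 1.0)
            s116 = np.clip(c1 - c16, -1.0, 1.0)
            s416 = np.clip(c4 - c16, -1.0, 1.0)
            d1 = s14 + s116
            d4 = -s14 + s416
            d16 = -s116 - s416
            dc[:, 0] += d1
            dc[:, 1:5] += d4[:, None]
            dc[:, 5:21] += d16[:, None]

            model.counter.backward((dc / b).ravel().astype(np.float32))
            opt.step()
            if pac_opt is not None:
                # fine-tuning still uses only class labels
                yb = np.array(
                    [
                        1.0 if examples[i].class_label is ClassLabel.PRESENT else 0.0
                        for i in idx
                    ],
                    dtype=np.float32,
                )
                pac_opt.zero_grad()
                logits = model.pac.forward_logits(
                    patch_all[idx * N_BRANCHES], train=True
                )
                p = np.asarray(sigmoid(logits))
                model.pac.backward(((p - yb) / b).astype(np.float32))
                pac_opt.step()
        trace.append(
            WSCountLoss(
                l_pac_c=float(np.mean(pac_losses)), l_sp_c=float(np.mean(sp_losses))
            )
        )
    return model, trace


def predict_wscount(model: WSCountModel, tile: np.ndarray) -> CountPrediction:
    """Tile count from the scale-1 branch (or scale mean, per config)."""
    return model.predict(tile)


def pac_accuracy(model: WSCountModel | PACModel, dataset) -> float:
    """Held-out presence/absence accuracy of the classifier."""
    pac = model.pac if isinstance(model, WSCountModel) else model
    examples = _coerce_weak_examples(dataset)
    batch = resize_batch(to_batch([ex.image for ex in examples]), pac.input_px)
    probs = pac.forward_batch(batch)
    pred = probs >= 0.5
    truth = np.array([ex.class_label is ClassLabel.PRESENT for ex in examples])
    return float(np.mean(pred == truth))
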