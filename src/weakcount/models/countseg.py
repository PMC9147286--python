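"""CountSeg: density-map counting under image-level lower-count supervision.

A shared backbone feature map passes through a 1×1 convolution (60
channels by default); half the channels feed a classification branch
(1×1 conv → confidence map, spatial-max pooled to a presence score) and
half a density branch (1×1 conv → rectified density map whose sum is the
predicted count). Training is joint, with three unweighted terms::

    L = L_class + L_spatial + L_global

* ``L_class`` — binary cross-entropy of the pooled presence score
  against the class label.
* ``L_global`` — squared error between the density sum and the count
  when the count is inside the subitizing range; beyond it only a hinge
  penalizing *under*-estimation below ``subitizing_max + 1`` (the
  image-level lower-count regime: the exact count is never consumed).
* ``L_spatial`` — cross-entropy between the min-max-normalized density
  map and a pseudo ground truth: the count-capped strongest local maxima
  of the confidence map (non-maximum suppression within a configurable
  neighborhood). Peaks from the classifier alone carry many false
  positives; capping at the known count is what filters them.

Supervision consumed: class labels and range-capped counts only — never
point coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
from scipy.ndimage import maximum_filter

from ..annotations import ClassLabel
from ..nn.layers import BatchNorm2d, Conv2d, ReLU, Sequential, sigmoid
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

logger = logging.getLogger(__name__)
_peak_shortfalls_seen: set[tuple[int, int]] = set()

__all__ = [
    "CountSegConfig",
    "CountSegModel",
    "DensityMap",
    "CountSegLoss",
    "build_countseg",
    "countseg_forward",
    "loss_class",
    "loss_global",
    "loss_spatial",
    "make_pseudo_ground_truth",
    "peak_instances",
    "train_countseg",
    "predict_countseg",
]


@dataclass(frozen=True)
class CountSegConfig:
    backbone: str = "tiny_cnn"
    shared_channels: int = 60  # split half/half between the two branches
    subitizing_max: int = 10
    peak_neighborhood_px: int = 3  # NMS radius in density-map cells
    input_size_px: int = 64
    learning_rate: float = 1e-3  # SGD 0.001 is the full-scale default
    optimizer: str = "sgd"
    epochs: int = 15
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shared_channels % 2:
            raise ValueError("shared_channels must be even (half per branch)")
        if self.subitizing_max < 1:
            raise ValueError("subitizing_max must be >= 1")


@dataclass
class DensityMap:
    """Nonnegative spatial map; its sum is the predicted global count."""

    values: np.ndarray
    stride_px: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if (self.values < 0).any():
            raise ValueError("density values must be nonnegative")

    @property
    def global_count(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class CountSegLoss:
    l_class: float
    l_spatial: float
    l_global: float

    @property
    def total(self) -> float:
        return self.l_class + self.l_spatial + self.l_global


class _LeakyRectifier:
    """Forward ReLU; backward with a small slope on dead cells.

    The density map must be nonnegative, but a hard rectifier silences
    the global count loss whenever the whole map is driven to zero (the
    spatial loss does exactly that early in training). A leaky backward
    pass keeps the count gradient able to revive dead density cells
    without ever producing negative densities.
    """

    def __init__(self, slope: float = 0.1) -> None:
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy).astype(np.float32)


class CountSegModel:
    """Shared features split between classification and density branches."""

    def __init__(self, config: CountSegConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.trunk, cout, self.stride = build_backbone(config.backbone, rng)
        ch = config.shared_channels
        self.shared = Sequential(Conv2d(cout, ch, 1, rng), BatchNorm2d(ch), ReLU())
        self.half = ch // 2
        self.cls_conv = Conv2d(self.half, 1, 1, rng)
        self.den_conv = Conv2d(self.half, 1, 1, rng)
        self.den_relu = _LeakyRectifier()

    def params(self):
        return (
            self.trunk.params()
            + self.shared.params()
            + self.cls_conv.params()
            + self.den_conv.params()
        )

    def state(self):
        out = {f"trunk.{k}": v for k, v in self.trunk.state().items()}
        out.update({f"shared.{k}": v for k, v in self.shared.state().items()})
        return out

    def forward(
        self, batch: np.ndarray, train: bool = False
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Returns (class scores (B,), confidence maps (B,h,w),
        densities (B,h,w))."""
        feats = self.trunk.forward(batch, train=train)
        shared = self.shared.forward(feats, train=train)
        conf = self.cls_conv.forward(shared[:, : self.half], train=train)[:, 0]
        dens = self.den_relu.forward(
            self.den_conv.forward(shared[:, self.half :], train=train), train=train
        )[:, 0]
        b, h, w = conf.shape
        flat = conf.reshape(b, -1)
        self._argmax = flat.argmax(axis=1)
        self._shape = (b, h, w)
        scores = flat[np.arange(b), self._argmax]
        return scores, conf, dens

    def backward(self, dscores: np.ndarray, ddens: np.ndarray) -> None:
        """Backprop through both branches into the shared trunk.

        ``dscores``: gradient on the max-pooled class score, routed to the
        argmax cell. ``ddens``: gradient on the rectified density map.
        """
        b, h, w = self._shape
        dconf = np.zeros((b, h * w), dtype=np.float32)
        dconf[np.arange(b), self._argmax] = dscores
        d_cls_half = self.cls_conv.backward(dconf.reshape(b, 1, h, w))
        dden = self.den_relu.backward(ddens[:, None].astype(np.float32))
        d_den_half = self.den_conv.backward(dden)
        dshared = np.concatenate([d_cls_half, d_den_half], axis=1)
        self.trunk.backward(self.shared.backward(dshared))

    def predict(self, tile: np.ndarray) -> CountPrediction:
        _, _, dens = self.forward(
            resize_batch(to_batch([tile]), self.config.input_size_px), train=False
        )
        return CountPrediction(count_real=float(dens[0].sum()), response_maps=dens)

    def density(self, tile: np.ndarray) -> DensityMap:
        _, _, dens = self.forward(
            resize_batch(to_batch([tile]), self.config.input_size_px), train=False
        )
        return DensityMap(values=dens[0].astype(np.float64), stride_px=self.stride)

    def save(self, path) -> None:
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        arrays.update({f"state.{k}": v for k, v in self.state().items()})
        save_params(path, arrays, {"kind": "countseg", "config": asdict(self.config)})

    @classmethod
    def load(cls, path) -> "CountSegModel":
        arrays, meta = load_params(path)
        model = cls(CountSegConfig(**meta["config"]))
        for i, p in enumerate(model.params()):
            p.value[...] = arrays[f"param_{i}"]
        for k, v in model.state().items():
            v[...] = arrays[f"state.{k}"]
        return model


def build_countseg(config: CountSegConfig) -> CountSegModel:
    return CountSegModel(config)


def countseg_forward(
    model: CountSegModel, tile: np.ndarray
) -> tuple[float, np.ndarray, DensityMap]:
    """(class score, confidence map, density map) for one tile."""
    batch = resize_batch(to_batch([tile]), model.config.input_size_px)
    scores, conf, dens = model.forward(batch, train=False)
    return (
        float(scores[0]),
        conf[0],
        DensityMap(values=dens[0].astype(np.float64), stride_px=model.stride),
    )


def loss_class(
    class_score: float,
    class_label: ClassLabel | str,
    score_is_probability: bool = False,
) -> float:
    """Binary cross-entropy of the pooled presence score.

    ``class_score`` is a logit unless ``score_is_probability`` is set.
    Exact zeros are returned for perfectly confident correct scores.
    """
    label = ClassLabel(class_label)
    y = 1.0 if label is ClassLabel.PRESENT else 0.0
    p = float(class_score) if score_is_probability else float(sigmoid(class_score))
    if not (0.0 <= p <= 1.0):
        raise ValueError("probability outside [0, 1]")
    if y == 1.0:
        return 0.0 if p == 1.0 else float(-np.log(max(p, 1e-300)))
    return 0.0 if p == 0.0 else float(-np.log(max(1.0 - p, 1e-300)))


def loss_global(
    density: DensityMap | np.ndarray,
    count: int,
    subitizing_max: int = 10,
    discard_above: int = 15,
) -> float:
    """Count loss: exact inside the subitizing range, hinge beyond.

    For ``count ≤ subitizing_max`` the squared error of the density sum;
    otherwise ``max(0, (subitizing_max+1) − Σdensity)²`` — the density
    only has to reach the lower bound, so only under-estimation beyond
    the subitizing range is penalized.
    """
    if count < 0:
        raise ValueError("count must be nonnegative")
    if count > discard_above:
        raise ValueError(
            f"count {count} beyond the countable range (> {discard_above}): dnc tile"
        )
    total = density.global_count if isinstance(density, DensityMap) else float(
        np.sum(density)
    )
    if count <= subitizing_max:
        return (total - count) ** 2
    return max(0.0, (subitizing_max + 1) - total) ** 2


def make_pseudo_ground_truth(
    confidence_map: np.ndarray, count: int, neighborhood_px: int = 3
) -> np.ndarray:
    """Boolean mask of the ``count`` strongest local maxima.

    Local maxima of the confidence map are ranked by value and selected
    greedily with non-maximum suppression (Chebyshev radius
    ``neighborhood_px``); construction is gradient-free. If fewer maxima
    exist than ``count``, all are marked and a warning is logged.
    """
    if count < 0:
        raise ValueError("count must be nonnegative")
    conf = np.asarray(confidence_map, dtype=np.float64)
    mask = np.zeros(conf.shape, dtype=bool)
    if count == 0:
        return mask
    size = 2 * neighborhood_px + 1
    is_max = conf == maximum_filter(conf, size=size, mode="nearest")
    cand = np.argwhere(is_max)
    order = np.argsort(conf[is_max])[::-1]
    chosen: list[tuple[int, int]] = []
    for k in order:
        r, c = cand[k]
        if any(
            max(abs(r - r0), abs(c - c0)) <= neighborhood_px for r0, c0 in chosen
        ):
            continue
        chosen.append((int(r), int(c)))
        if len(chosen) == count:
            break
    if len(chosen) < count:
        # warn once per distinct shortfall; this fires on every dense tile
        # during training and would otherwise flood the log
        key = (len(chosen), count)
        level = logging.DEBUG if key in _peak_shortfalls_seen else logging.WARNING
        _peak_shortfalls_seen.add(key)
        logger.log(
            level,
            "pseudo ground truth: only %d separated maxima for count %d",
            len(chosen),
            count,
        )
    for r, c in chosen:
        mask[r, c] = True
    return mask


def _normalize(density: np.ndarray) -> np.ndarray:
    lo, hi = density.min(), density.max()
    if hi > lo:
        return (density - lo) / (hi - lo)
    return np.zeros_like(density)


_BCE_EPS = 1e-4  # clamp for imperfect cells; perfect cells contribute exactly 0


def loss_spatial(density: DensityMap | np.ndarray, peak_mask: np.ndarray) -> float:
    """Pixel-averaged cross-entropy between the min-max-normalized
    density map and the pseudo peak mask.

    A cell matching its target exactly (normalized value 1 on a peak,
    0 off a peak) contributes exactly zero; all other cells are clamped
    into ``[eps, 1−eps]`` before the log so a single saturated cell —
    min-max normalization always places one cell at 1 — cannot dominate
    the objective.
    """
    d = density.values if isinstance(density, DensityMap) else np.asarray(
        density, dtype=np.float64
    )
    mask = np.asarray(peak_mask, dtype=bool)
    if d.shape != mask.shape:
        raise ValueError(f"shape mismatch: {d.shape} vs {mask.shape}")
    n = _normalize(d)
    terms = np.zeros_like(n)
    pos = mask & (n < 1.0)
    neg = ~mask & (n > 0.0)
    terms[pos] = -np.log(np.maximum(n[pos], _BCE_EPS))
    terms[neg] = -np.log(np.maximum(1.0 - n[neg], _BCE_EPS))
    return float(terms.mean())


def _loss_spatial_grad(density: np.ndarray, peak_mask: np.ndarray) -> np.ndarray:
    """Subgradient of loss_spatial wrt the raw density values.

    The min-max normalization constants are treated as detached, and the
    ``1/(max−min)`` chain factor is clamped at 1: the loss is invariant
    to the map's scale, so near-flat maps would otherwise receive
    unbounded gradients that swamp the count (global) term.
    """
    d = np.asarray(density, dtype=np.float64)
    lo, hi = d.min(), d.max()
    rng = hi - lo
    if rng <= 0:
        return np.zeros_like(d)
    n = np.clip((d - lo) / rng, _BCE_EPS, 1 - _BCE_EPS)
    m = peak_mask.astype(np.float64)
    # clip the per-cell terms: the spatial loss steers where density mass
    # sits; the global term owns the total, and must not be overwhelmed
    dn = np.clip(-m / n + (1 - m) / (1 - n), -8.0, 8.0) / d.size
    return dn / max(rng, 1.0)


def peak_instances(
    density: DensityMap, threshold: float, neighborhood_px: int = 3
) -> list[tuple[float, float]]:
    """Instance locations: density peaks above ``threshold`` after NMS,
    mapped to image pixel coordinates via the map stride."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    d = density.values
    size = 2 * neighborhood_px + 1
    is_max = (d == maximum_filter(d, size=size, mode="nearest")) & (d > threshold)
    cand = np.argwhere(is_max)
    order = np.argsort(d[is_max])[::-1]
    chosen: list[tuple[int, int]] = []
    for k in order:
        r, c = cand[k]
        if any(
            max(abs(r - r0), abs(c - c0)) <= neighborhood_px for r0, c0 in chosen
        ):
            continue
        chosen.append((int(r), int(c)))
    s = density.stride_px
    return [((c + 0.5) * s - 0.5, (r + 0.5) * s - 0.5) for r, c in chosen]


def train_countseg(
    model: CountSegModel,
    examples: list[TrainingExample],
    config: CountSegConfig | None = None,
) -> tuple[CountSegModel, list[CountSegLoss]]:
    """Joint training with class + spatial + global losses (ILC regime).

    Consumes each example's class label and its range-capped count
    (``TrainingExample.ilc_count``) — never point coordinates.
    """
    cfg = config or model.config
    if not examples:
        raise ValueError("empty training dataset")
    labels = np.array(
        [1.0 if ex.class_label is ClassLabel.PRESENT else 0.0 for ex in examples],
        dtype=np.float64,
    )
    ilc = np.array(
        [ex.ilc_count(cfg.subitizing_max) for ex in examples], dtype=np.float64
    )
    batch_all = resize_batch(to_batch([ex.image for ex in examples]), cfg.input_size_px)

    rng = np.random.default_rng(cfg.seed + 7)
    opt = make_optimizer(cfg.optimizer, model.params(), cfg.learning_rate)
    trace = []
    n = len(examples)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        l_cls, l_sp, l_gl = [], [], []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb, cb = batch_all[idx], labels[idx], ilc[idx]
            b = len(idx)
            opt.zero_grad()
            scores, conf, dens = model.forward(xb, train=True)
            probs = np.asarray(sigmoid(scores), dtype=np.float64)

            eps = 1e-12
            l_cls.append(
                float(
                    -np.mean(
                        yb * np.log(probs + eps) + (1 - yb) * np.log(1 - probs + eps)
                    )
                )
            )
            dscores = (probs - yb) / b

            sums = dens.reshape(b, -1).sum(axis=1)
            inside = cb <= cfg.subitizing_max
            bound = cfg.subitizing_max + 1
            gl = np.where(
                inside,
                (sums - cb) ** 2,
                np.maximum(0.0, bound - sums) ** 2,
            )
            l_gl.append(float(gl.mean()))
            dsum = np.where(
                inside, 2.0 * (sums - cb), -2.0 * np.maximum(0.0, bound - sums)
            )
            ddens = np.broadcast_to(
                (dsum / b)[:, None, None], dens.shape
            ).astype(np.float64).copy()

            # spatial term on presence tiles only: an absent tile has no
            # peaks to localize, and its density is already pulled to zero
            # by the global term
            sp_sum = 0.0
            for i in range(b):
                if cb[i] < 1:
                    continue
                peaks = make_pseudo_ground_truth(
                    conf[i], int(cb[i]), cfg.peak_neighborhood_px
                )
                sp_sum += loss_spatial(dens[i].astype(np.float64), peaks)
                ddens[i] += _loss_spatial_grad(dens[i], peaks) / b
            l_sp.append(sp_sum / b)

            model.backward(dscores.astype(np.float32), ddens)
            opt.step()
        trace.append(
            CountSegLoss(
                l_class=float(np.mean(l_cls)),
                l_spatial=float(np.mean(l_sp)),
                l_global=float(np.mean(l_gl)),
            )
        )
    return model, trace


def predict_countseg(model: CountSegModel, tile: np.ndarray) -> CountPrediction:
    """Global count: the sum of the predicted density map."""
    return model.predict(tile)
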