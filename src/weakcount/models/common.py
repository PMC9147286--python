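"""Shared model plumbing: predictions, training examples, supervision audit.

The three counters consume different supervision — S-Count reads integer
counts, WS-Count only presence/absence labels, CountSeg class labels plus
counts capped at the subitizing range. :class:`TrainingExample` exposes
each label through a property that reports the access to an optional
:class:`SupervisionLog`, so a test (or a cautious user) can *prove* what
a training run consumed rather than trust documentation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import zoom as _ndzoom

from ..annotations import ClassLabel, derive_class_label

__all__ = [
    "CountPrediction",
    "SupervisionLog",
    "TrainingExample",
    "examples_from_scenes",
    "to_batch",
    "resize_batch",
    "save_params",
    "load_params",
]


@dataclass
class CountPrediction:
    """A model's count for one tile: real-valued and rounded forms."""

    count_real: float
    response_maps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.count_real = float(max(0.0, self.count_real))

    @property
    def count_int(self) -> int:
        return int(round(self.count_real))


class SupervisionLog:
    """Records which label fields a training run read, and which counts."""

    def __init__(self) -> None:
        self.field_accesses: Counter[str] = Counter()
        self.counts_seen: list[int] = []

    def record(self, fieldname: str, value=None) -> None:
        self.field_accesses[fieldname] += 1
        if fieldname in ("count", "ilc_count") and value is not None:
            self.counts_seen.append(int(value))

    def accessed(self, fieldname: str) -> bool:
        return self.field_accesses[fieldname] > 0


@dataclass
class TrainingExample:
    """One tile with its labels, behind audit-reporting accessors."""

    image_: np.ndarray
    count_: int | None = None
    class_label_: ClassLabel | None = None
    points_: list[tuple[float, float]] | None = None
    tile_id: str = ""
    audit: SupervisionLog | None = field(default=None, repr=False)

    @property
    def image(self) -> np.ndarray:
        return self.image_

    @property
    def count(self) -> int:
        if self.audit is not None:
            self.audit.record("count", self.count_)
        if self.count_ is None:
            raise ValueError(f"{self.tile_id}: no count supervision available")
        return self.count_

    def ilc_count(self, subitizing_max: int) -> int:
        """Image-level lower count: the true count inside the subitizing
        range, else the capped value ``subitizing_max + 1`` (meaning
        "at least this many")."""
        if self.count_ is None:
            raise ValueError(f"{self.tile_id}: no count supervision available")
        capped = min(self.count_, subitizing_max + 1)
        if self.audit is not None:
            self.audit.record("ilc_count", capped)
        return capped

    @property
    def class_label(self) -> ClassLabel:
        if self.audit is not None:
            self.audit.record("class_label")
        if self.class_label_ is not None:
            return self.class_label_
        if self.count_ is None:
            raise ValueError(f"{self.tile_id}: no class supervision available")
        return derive_class_label(self.count_)

    @property
    def points(self) -> list[tuple[float, float]]:
        if self.audit is not None:
            self.audit.record("points")
        if self.points_ is None:
            raise ValueError(f"{self.tile_id}: no point supervision available")
        return self.points_


def examples_from_scenes(
    scenes, audit: SupervisionLog | None = None
) -> list[TrainingExample]:
    """Wrap synthetic scenes as training examples with full ground truth."""
    return [
        TrainingExample(
            image_=s.image,
            count_=s.count,
            points_=list(s.points),
            tile_id=f"scene_{i:04d}",
            audit=audit,
        )
        for i, s in enumerate(scenes)
    ]


def to_batch(images) -> np.ndarray:
    """Stack H×W×3 float images in [0,1] into an NCHW float32 batch."""
    arr = np.stack([np.asarray(im) for im in images]).astype(np.float32)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(f"expected N×H×W×3 images, got {arr.shape}")
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2))


def resize_batch(batch: np.ndarray, side: int) -> np.ndarray:
    """Bilinear resize of an NCHW batch to ``side × side``."""
    n, c, h, w = batch.shape
    if h == side and w == side:
        return batch
    out = _ndzoom(
        batch, (1, 1, side / h, side / w), order=1, mode="nearest", grid_mode=True
    )
    return np.ascontiguousarray(out.astype(np.float32))


def save_params(path: str | Path, arrays: dict[str, np.ndarray], meta: dict) -> None:
    """Checkpoint: one .npz of arrays plus a JSON-encoded config blob."""
    import json

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_params(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    import json

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(path) as data:
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
        meta = json.loads(bytes(data["__meta__"]).decode())
    return arrays, meta
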