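"""Point/mask annotation handling, label derivation and balancing.

Counting supervision in this package always flows from point marks: one
point per organ instance gives the integer count; the binary class label
(present/absent) and the count bin are *derived* from that count, never
stored independently. Count bins follow the subitizing convention: exact
counting is expected only inside the subitizing range ``[0, 10]``,
counts of 11–15 are a challenging band, and tiles above 15 are flagged
``dnc`` ("did not count") and excluded from training — they are kept in
files, never silently deleted.

Annotation files use the VGG Image Annotator (VIA) JSON export layout:
one entry per image with a list of regions whose ``shape_attributes``
are ``point`` (cx, cy) or ``polygon`` (all_points_x, all_points_y).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ClassLabel",
    "CountBin",
    "PointLabel",
    "MaskLabel",
    "TileAnnotation",
    "read_via_export",
    "write_via_export",
    "derive_class_label",
    "bin_count",
    "rotate_point_90ccw",
    "balance_by_rotation",
    "write_manifest",
    "read_manifest",
]


class ClassLabel(str, Enum):
    PRESENT = "present"
    ABSENT = "absent"


class CountBin(str, Enum):
    ZERO = "zero"
    B1_5 = "b1_5"
    B6_10 = "b6_10"
    B11_15 = "b11_15"
    DNC = "dnc"  # did not count: beyond the retained range, excluded from training


@dataclass(frozen=True)
class PointLabel:
    x: float
    y: float
    instance_id: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("point coordinates must be finite")
        if self.x < 0 or self.y < 0:
            raise ValueError("point coordinates must be nonnegative")


@dataclass(frozen=True)
class MaskLabel:
    polygon: tuple[tuple[float, float], ...]
    class_name: str = "boll"

    def __post_init__(self) -> None:
        if len(self.polygon) < 3:
            raise ValueError("polygon needs at least 3 vertices")


def derive_class_label(count: int) -> ClassLabel:
    """Presence/absence from a count: present ⟺ count > 0."""
    if count < 0:
        raise ValueError("count must be nonnegative")
    return ClassLabel.PRESENT if count > 0 else ClassLabel.ABSENT


def bin_count(count: int, subitizing_max: int = 10, discard_above: int = 15) -> CountBin:
    """Count-bin category: 0 / [1,5] / [6,10] / [11,15] / dnc (>15)."""
    if count < 0:
        raise ValueError("count must be nonnegative")
    if count == 0:
        return CountBin.ZERO
    if count <= 5:
        return CountBin.B1_5
    if count <= subitizing_max:
        return CountBin.B6_10
    if count <= discard_above:
        return CountBin.B11_15
    return CountBin.DNC


@dataclass
class TileAnnotation:
    """Per-tile ground truth: points, optional masks, derived labels."""

    tile_id: str
    points: list[PointLabel] = field(default_factory=list)
    masks: list[MaskLabel] = field(default_factory=list)
    count: int | None = None
    subitizing_max: int = 10
    discard_above: int = 15

    def __post_init__(self) -> None:
        if self.count is None:
            self.count = len(self.points)
        elif self.points and self.count != len(self.points):
            raise ValueError(
                f"{self.tile_id}: count {self.count} != {len(self.points)} points"
            )
        if self.count < 0:
            raise ValueError("count must be nonnegative")

    @property
    def class_label(self) -> ClassLabel:
        return derive_class_label(self.count)

    @property
    def count_bin(self) -> CountBin:
        return bin_count(self.count, self.subitizing_max, self.discard_above)

    @property
    def is_dnc(self) -> bool:
        return self.count_bin is CountBin.DNC


def read_via_export(document: dict | str | Path) -> list[TileAnnotation]:
    """Parse a VIA JSON export into per-image annotations.

    ``document`` may be a parsed dict, a JSON string, or a file path.
    Point regions become :class:`PointLabel`, polygon regions
    :class:`MaskLabel`; other region shapes are skipped with a warning.
    """
    if isinstance(document, Path) or (
        isinstance(document, str) and not document.lstrip().startswith("{")
    ):
        document = Path(document).read_text()
    if isinstance(document, str):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed VIA JSON: {exc}") from exc
    entries = document.get("_via_img_metadata", document)

    annotations = []
    for key, entry in entries.items():
        name = entry.get("filename", key)
        points, masks = [], []
        for region in entry.get("regions", []):
            shape = region.get("shape_attributes", {})
            kind = shape.get("name")
            if kind == "point":
                if "cx" not in shape or "cy" not in shape:
                    raise ValueError(f"image {name!r}: point region missing cx/cy")
                points.append(
                    PointLabel(float(shape["cx"]), float(shape["cy"]), len(points))
                )
            elif kind == "polygon":
                xs, ys = shape.get("all_points_x"), shape.get("all_points_y")
                if xs is None or ys is None or len(xs) != len(ys):
                    raise ValueError(f"image {name!r}: polygon region missing coordinates")
                masks.append(
                    MaskLabel(tuple((float(x), float(y)) for x, y in zip(xs, ys)))
                )
            else:
                logger.warning("image %r: skipping region shape %r", name, kind)
        annotations.append(TileAnnotation(tile_id=name, points=points, masks=masks))
    return annotations


def write_via_export(
    annotations: list[TileAnnotation], path: str | Path | None = None
) -> dict:
    """Serialize annotations to the VIA export structure (optionally to disk)."""
    doc: dict = {}
    for anno in annotations:
        regions = [
            {
                "shape_attributes": {"name": "point", "cx": p.x, "cy": p.y},
                "region_attributes": {"instance_id": p.instance_id},
            }
            for p in anno.points
        ]
        regions += [
            {
                "shape_attributes": {
                    "name": "polygon",
                    "all_points_x": [v[0] for v in m.polygon],
                    "all_points_y": [v[1] for v in m.polygon],
                },
                "region_attributes": {"class": m.class_name},
            }
            for m in anno.masks
        ]
        doc[anno.tile_id] = {
            "filename": anno.tile_id,
            "size": -1,
            "regions": regions,
            "file_attributes": {},
        }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=1))
    return doc


def rotate_point_90ccw(x: float, y: float, side: int) -> tuple[float, float]:
    """Rotate a pixel coordinate 90° counter-clockwise in a square tile.

    Convention: (x, y) → (y, side − 1 − x), matching ``np.rot90(img, 1)``
    on the pixel array (verified by the one-hot commutation test).
    """
    return (y, side - 1 - x)


def _rotate_annotation(anno: TileAnnotation, side: int, k: int) -> TileAnnotation:
    points = anno.points
    masks = anno.masks
    for _ in range(k):
        points = [
            PointLabel(*rotate_point_90ccw(p.x, p.y, side), p.instance_id)
            for p in points
        ]
        masks = [
            MaskLabel(
                tuple(rotate_point_90ccw(x, y, side) for x, y in m.polygon),
                m.class_name,
            )
            for m in masks
        ]
    return TileAnnotation(
        tile_id=f"{anno.tile_id}@rot{90 * k}",
        points=points,
        masks=masks,
        subitizing_max=anno.subitizing_max,
        discard_above=anno.discard_above,
    )


def balance_by_rotation(
    dataset: list[tuple[np.ndarray, TileAnnotation]],
    target_bins: set[CountBin],
    n_samples: int | None = None,
    seed: int = 0,
) -> list[tuple[np.ndarray, TileAnnotation]]:
    """Augment under-represented count bins with 90°/180°/270° rotations.

    Tiles whose count bin is in ``target_bins`` are (all, or a seeded
    random sample of ``n_samples``) rotated three times; counts and class
    labels are unchanged and point/polygon coordinates are rotated with
    the same convention as the pixel array.
    """
    eligible = [
        i for i, (_tile, anno) in enumerate(dataset) if anno.count_bin in target_bins
    ]
    if n_samples is not None and eligible:
        rng = np.random.default_rng(seed)
        eligible = list(rng.choice(eligible, size=min(n_samples, len(eligible)), replace=False))
    augmented = list(dataset)
    for i in eligible:
        tile, anno = dataset[i]
        h, w = tile.shape[:2]
        if h != w:
            raise ValueError(f"{anno.tile_id}: rotation balancing needs square tiles")
        for k in (1, 2, 3):
            augmented.append((np.rot90(tile, k).copy(), _rotate_annotation(anno, w, k)))
    return augmented


def write_manifest(annotations: list[TileAnnotation], path: str | Path) -> None:
    """CSV manifest (tile_id, count, class_label, count_bin) for splits."""
    import pandas as pd

    pd.DataFrame(
        {
            "tile_id": [a.tile_id for a in annotations],
            "count": [a.count for a in annotations],
            "class_label": [a.class_label.value for a in annotations],
            "count_bin": [a.count_bin.value for a in annotations],
        }
    ).to_csv(path, index=False)


def read_manifest(path: str | Path):
    import pandas as pd

    return pd.read_csv(path)
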