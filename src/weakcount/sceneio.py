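"""Write synthetic scenes as PNG images plus VIA-style annotations.

Bridges the scene generator and the annotations module: blob masks are
polygonized (marching squares on the mask boundary) into VIA polygon
regions and blob centers become point regions, so synthetic data
round-trips through the same annotation reader as real exports.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image
from skimage import measure

from .annotations import MaskLabel, PointLabel, TileAnnotation, write_via_export
from .synthetic import Scene

__all__ = ["scene_to_annotation", "save_scene_png", "save_scenes"]

_MAX_POLY_VERTICES = 32


def _mask_to_polygon(mask: np.ndarray) -> tuple[tuple[float, float], ...]:
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:  # mask clipped to almost nothing; fall back to bbox
        rows, cols = np.nonzero(mask)
        r0, r1, c0, c1 = rows.min(), rows.max(), cols.min(), cols.max()
        return ((c0, r0), (c1, r0), (c1, r1), (c0, r1))
    contour = max(contours, key=len)  # (row, col) vertices
    step = max(1, len(contour) // _MAX_POLY_VERTICES)
    pts = contour[::step]
    return tuple((float(c), float(r)) for r, c in pts)


def scene_to_annotation(scene: Scene, tile_id: str) -> TileAnnotation:
    """Exact ground truth of a scene as a TileAnnotation."""
    points = [
        PointLabel(float(x), float(y), i) for i, (x, y) in enumerate(scene.points)
    ]
    masks = [MaskLabel(_mask_to_polygon(m)) for m in scene.masks]
    return TileAnnotation(tile_id=tile_id, points=points, masks=masks)


def save_scene_png(scene: Scene, path: str | Path) -> None:
    arr = np.clip(scene.image * 255.0 + 0.5, 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def save_scenes(
    scenes: list[Scene], out_dir: str | Path, prefix: str = "scene"
) -> Path:
    """Write scene PNGs and one VIA JSON export; returns the JSON path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    annotations = []
    for i, scene in enumerate(scenes):
        name = f"{prefix}_{i:04d}.png"
        save_scene_png(scene, out_dir / name)
        annotations.append(scene_to_annotation(scene, name))
    json_path = out_dir / f"{prefix}_via.json"
    write_via_export(annotations, json_path)
    return json_path
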