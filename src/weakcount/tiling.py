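"""Decompose full plant images into fixed-size zero-padded tiles.

A source image of any size is covered by a non-overlapping grid of
``tile_size × tile_size`` tiles; pixels beyond the source extent (bottom
and right edges only) are zero. Tile ``(r, c)`` owns the half-open pixel
window ``[c·T, (c+1)·T) × [r·T, (r+1)·T)``, so every point annotation
belongs to exactly one tile and per-tile counts always sum to the total —
the conservation property that makes plant-level totals (the sum of tile
counts) exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TileGrid",
    "ImageTile",
    "tile_image",
    "assign_points_to_tiles",
    "aggregate_plant_count",
    "stitch_tiles",
]


@dataclass(frozen=True)
class TileGrid:
    source_height_px: int
    source_width_px: int
    tile_size_px: int
    n_rows: int
    n_cols: int
    pad_bottom_px: int
    pad_right_px: int

    @classmethod
    def for_image(cls, height: int, width: int, tile_size: int) -> "TileGrid":
        if height < 1 or width < 1 or tile_size < 1:
            raise ValueError("image dimensions and tile size must be >= 1")
        n_rows = math.ceil(height / tile_size)
        n_cols = math.ceil(width / tile_size)
        return cls(
            source_height_px=height,
            source_width_px=width,
            tile_size_px=tile_size,
            n_rows=n_rows,
            n_cols=n_cols,
            pad_bottom_px=n_rows * tile_size - height,
            pad_right_px=n_cols * tile_size - width,
        )


@dataclass
class ImageTile:
    pixels: np.ndarray  # (T, T, 3)
    grid_row: int
    grid_col: int
    origin_xy: tuple[int, int]  # (x0, y0) offset in the source image
    source_id: str = ""


def tile_image(
    image: np.ndarray, tile_size_px: int, source_id: str = ""
) -> tuple[TileGrid, list[ImageTile]]:
    """Split an H×W×3 image into zero-padded tiles in row-major order."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 image, got shape {image.shape}")
    h, w = image.shape[:2]
    grid = TileGrid.for_image(h, w, tile_size_px)
    padded = np.zeros(
        (h + grid.pad_bottom_px, w + grid.pad_right_px, 3), dtype=image.dtype
    )
    padded[:h, :w] = image
    t = tile_size_px
    tiles = [
        ImageTile(
            pixels=padded[r * t : (r + 1) * t, c * t : (c + 1) * t].copy(),
            grid_row=r,
            grid_col=c,
            origin_xy=(c * t, r * t),
            source_id=source_id,
        )
        for r in range(grid.n_rows)
        for c in range(grid.n_cols)
    ]
    return grid, tiles


def assign_points_to_tiles(
    points: list[tuple[float, float]], grid: TileGrid
) -> dict[tuple[int, int], int]:
    """Count points per tile under the half-open window rule.

    A point on a tile boundary (x or y an exact multiple of the tile
    size) belongs to the higher-index tile, so the assignment is a
    partition and counts always sum to ``len(points)``.
    """
    t = grid.tile_size_px
    counts = {
        (r, c): 0 for r in range(grid.n_rows) for c in range(grid.n_cols)
    }
    for x, y in points:
        if not (0 <= x < grid.source_width_px and 0 <= y < grid.source_height_px):
            raise ValueError(
                f"point ({x}, {y}) outside source extent "
                f"{grid.source_width_px}×{grid.source_height_px}"
            )
        counts[(int(y // t), int(x // t))] += 1
    return counts


def aggregate_plant_count(tile_counts) -> float:
    """Plant-level count: the arithmetic sum of per-tile counts."""
    total = 0.0
    for c in tile_counts:
        if c < 0:
            raise ValueError(f"negative tile count {c}")
        total += c
    return total


def stitch_tiles(grid: TileGrid, tiles: list[ImageTile]) -> np.ndarray:
    """Reassemble the source image from its tiles (padding cropped)."""
    t = grid.tile_size_px
    canvas = np.zeros(
        (grid.n_rows * t, grid.n_cols * t, 3), dtype=tiles[0].pixels.dtype
    )
    for tile in tiles:
        r, c = tile.grid_row, tile.grid_col
        canvas[r * t : (r + 1) * t, c * t : (c + 1) * t] = tile.pixels
    return canvas[: grid.source_height_px, : grid.source_width_px]
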