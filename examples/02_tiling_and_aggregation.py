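"""Tile a full-scale plant image and aggregate per-tile counts.

A 160x224 synthetic "plant" is cut into zero-padded 64px tiles; ground
truth points are assigned to tiles by the half-open window rule and the
per-tile counts are summed back to the plant total — exactly, because
the tile windows partition the image.
"""

import dataclasses

from weakcount.synthetic import benchmark_config, generate_scene
from weakcount.tiling import aggregate_plant_count, assign_points_to_tiles, tile_image

cfg = dataclasses.replace(
    benchmark_config(seed=3),
    image_height_px=160,
    image_width_px=224,
    count_range=(8, 14),
)
scene = generate_scene(cfg)
grid, tiles = tile_image(scene.image, 64)
print(f"plant image {cfg.image_height_px}x{cfg.image_width_px}, true count {scene.count}")
print(f"grid: {grid.n_rows}x{grid.n_cols} tiles, pads bottom={grid.pad_bottom_px}px right={grid.pad_right_px}px")

per_tile = assign_points_to_tiles(scene.points, grid)
for (r, c), n in sorted(per_tile.items()):
    if n:
        print(f"  tile ({r},{c}): {n} bolls")
total = aggregate_plant_count(per_tile.values())
print(f"sum of tile counts = {total} (equals the true count: conservation)")
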