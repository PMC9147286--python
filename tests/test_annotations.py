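"""Annotation I/O, label derivation, count bins, rotation balancing."""

import json

import numpy as np
import pytest

from weakcount.annotations import (
    ClassLabel,
    CountBin,
    PointLabel,
    TileAnnotation,
    balance_by_rotation,
    bin_count,
    derive_class_label,
    read_via_export,
    rotate_point_90ccw,
    write_via_export,
)
from weakcount.sceneio import scene_to_annotation
from weakcount.synthetic import benchmark_config, generate_scene


class TestLabels:
    @pytest.mark.parametrize(
        "count,expected",
        [(0, ClassLabel.ABSENT), (1, ClassLabel.PRESENT), (5, ClassLabel.PRESENT)],
    )
    def test_presence_iff_positive_count(self, count, expected):
        assert derive_class_label(count) is expected

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            derive_class_label(-1)

    @pytest.mark.parametrize(
        "count,expected",
        [
            (0, CountBin.ZERO),
            (3, CountBin.B1_5),
            (5, CountBin.B1_5),
            (6, CountBin.B6_10),
            (10, CountBin.B6_10),
            (11, CountBin.B11_15),
            (15, CountBin.B11_15),
            (16, CountBin.DNC),
            (40, CountBin.DNC),
        ],
    )
    def test_subitizing_bin_edges(self, count, expected):
        assert bin_count(count) is expected

    def test_annotation_consistency(self):
        anno = TileAnnotation("t", points=[PointLabel(1, 2), PointLabel(3, 4)])
        assert anno.count == 2
        assert anno.class_label is ClassLabel.PRESENT
        assert anno.count_bin is CountBin.B1_5
        with pytest.raises(ValueError):
            TileAnnotation("t", points=[PointLabel(1, 2)], count=5)

    def test_dnc_flagged_not_dropped(self):
        anno = TileAnnotation("t", count=20)
        assert anno.is_dnc and anno.count == 20


class TestViaExport:
    def test_point_regions_counted(self):
        doc = {
            "img.png": {
                "filename": "img.png",
                "regions": [
                    {"shape_attributes": {"name": "point", "cx": 10, "cy": 20}},
                    {"shape_attributes": {"name": "point", "cx": 30, "cy": 40}},
                ],
            }
        }
        (anno,) = read_via_export(doc)
        assert anno.count == 2 and anno.class_label is ClassLabel.PRESENT

    def test_zero_regions_is_absent(self):
        (anno,) = read_via_export({"bg.png": {"filename": "bg.png", "regions": []}})
        assert anno.count == 0 and anno.class_label is ClassLabel.ABSENT

    def test_malformed_json_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            read_via_export("{not json")

    def test_missing_coordinates_names_image(self):
        doc = {"x.png": {"filename": "x.png", "regions": [{"shape_attributes": {"name": "point", "cx": 5}}]}}
        with pytest.raises(ValueError, match="x.png"):
            read_via_export(doc)

    def test_unknown_shape_skipped_with_warning(self, caplog):
        doc = {
            "y.png": {
                "filename": "y.png",
                "regions": [
                    {"shape_attributes": {"name": "ellipse", "cx": 1, "cy": 1}},
                    {"shape_attributes": {"name": "point", "cx": 2, "cy": 2}},
                ],
            }
        }
        import logging

        with caplog.at_level(logging.WARNING, logger="weakcount.annotations"):
            (anno,) = read_via_export(doc)
        assert anno.count == 1
        assert any("ellipse" in rec.message for rec in caplog.records)

    def test_synthetic_writer_round_trip(self, tmp_path):
        scene = generate_scene(benchmark_config(seed=21))
        anno = scene_to_annotation(scene, "scene.png")
        path = tmp_path / "via.json"
        write_via_export([anno], path)
        (parsed,) = read_via_export(json.loads(path.read_text()))
        assert parsed.count == scene.count
        for p, (x, y) in zip(parsed.points, scene.points):
            assert abs(p.x - x) < 1e-6 and abs(p.y - y) < 1e-6
        assert len(parsed.masks) == len(scene.masks)


class TestRotationBalancing:
    def test_rotation_formula_matches_array_rotation(self):
        # one-hot commutation: the rotated point lands on the rotated pixel
        side = 500
        img = np.zeros((side, side, 3))
        x, y = 10, 20
        img[y, x] = 1.0
        rot = np.rot90(img, 1)
        xr, yr = rotate_point_90ccw(x, y, side)
        assert rot[int(yr), int(xr), 0] == 1.0

    def test_quadruple_rotation_is_identity(self):
        pt = (37.5, 112.25)
        side = 128
        out = pt
        for _ in range(4):
            out = rotate_point_90ccw(*out, side)
        assert out == pt

    def test_selected_bin_tiles_quadrupled_counts_unchanged(self):
        import dataclasses

        scene = generate_scene(
            dataclasses.replace(
                benchmark_config(seed=8),
                count_range=(7, 7),
                occlusion_probability=0.5,
            )
        )
        anno = scene_to_annotation(scene, "t7.png")
        out = balance_by_rotation([(scene.image, anno)], {CountBin.B6_10})
        assert len(out) == 4
        assert all(a.count == 7 for _img, a in out)
        assert all(a.class_label is ClassLabel.PRESENT for _img, a in out)
        # rotated points still sit on their (rotated) blobs
        for img, a in out[1:]:
            for p in a.points:
                patch = img[
                    max(0, int(p.y) - 1) : int(p.y) + 2,
                    max(0, int(p.x) - 1) : int(p.x) + 2,
                ]
                assert patch.max() > 0.5  # a bright boll pixel under the point

    def test_no_target_bins_returns_unchanged(self):
        scene = generate_scene(benchmark_config(seed=3))
        anno = scene_to_annotation(scene, "t.png")
        data = [(scene.image, anno)]
        assert balance_by_rotation(data, {CountBin.B11_15}) == data

    def test_non_square_tile_rejected(self):
        anno = TileAnnotation("t", count=7)
        with pytest.raises(ValueError, match="square"):
            balance_by_rotation([(np.zeros((10, 20, 3)), anno)], {CountBin.B6_10})
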