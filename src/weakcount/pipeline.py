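"""End-to-end orchestration: synthesize/tile/predict/aggregate/evaluate.

A single :class:`RunConfig` drives the whole plant-counting workflow:
full-scale (synthetic) plant images are decomposed into tiles, a counting
model predicts per tile, tile counts are summed to plant totals, and a
JSON report plus a reproducibility manifest (config hash, seed, package
version) are written. One global seed fans out to per-stage seeds by a
fixed derivation, so each stage is independently reproducible and two
runs with the same config produce byte-identical reports for
deterministic (frozen) models.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .evaluation import evaluate_plants
from .synthetic import SceneConfig, benchmark_config, generate_scene
from .tiling import aggregate_plant_count, assign_points_to_tiles, tile_image

__all__ = ["RunConfig", "run_end2end", "stage_seed", "load_model"]

_MODEL_KINDS = ("oracle", "scount", "wscount", "countseg")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2³¹ derived from the run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class RunConfig:
    model: str = "oracle"  # oracle = ground-truth per-tile counts
    checkpoint: str | None = None
    tile_size_px: int = 64
    subitizing_max: int = 10
    discard_above: int = 15
    seed: int = 0
    n_plants: int = 3
    plant_grid: int = 2  # plants span plant_grid × plant_grid tiles
    plant_count_range: tuple[int, int] = (4, 12)
    out_dir: str = "weakcount_run"

    def __post_init__(self) -> None:
        if self.model not in _MODEL_KINDS:
            raise ValueError(f"model must be one of {_MODEL_KINDS}")
        if self.model != "oracle" and not self.checkpoint:
            raise ValueError(f"model {self.model!r} requires a checkpoint path")


def load_model(kind: str, checkpoint: str | Path):
    """Load a trained counting model of the given kind from disk."""
    from .models.countseg import CountSegModel
    from .models.scount import SCountModel
    from .models.wscount import WSCountModel

    path = Path(checkpoint)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    loader = {
        "scount": SCountModel,
        "wscount": WSCountModel,
        "countseg": CountSegModel,
    }[kind]
    return loader.load(path)


def _plant_scene_config(cfg: RunConfig, seed: int) -> SceneConfig:
    side = cfg.tile_size_px * cfg.plant_grid
    base = benchmark_config(seed=seed, tile_px=cfg.tile_size_px)
    return dataclasses.replace(
        base,
        image_height_px=side,
        image_width_px=side,
        count_range=cfg.plant_count_range,
        seed=seed,
    )


def run_end2end(config: RunConfig) -> dict:
    """Run tile → predict → aggregate → evaluate; returns the report dict.

    Artifacts written under ``config.out_dir``: ``manifest.json`` (config,
    seed, version, config hash) and ``report.json`` (per-plant totals and
    per-tile counts). Any stage failure is re-raised naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:
            raise RuntimeError(f"end2end stage {name!r} failed: {exc}") from exc

    # --- synth: seeded full-scale plants with exact ground truth --------
    def _synth():
        plants = []
        for i in range(config.n_plants):
            scfg = _plant_scene_config(config, stage_seed(config.seed, f"synth{i}"))
            plants.append((f"plant_{i:03d}", generate_scene(scfg)))
        return plants

    plants = _stage("synth", _synth)

    # --- model ----------------------------------------------------------
    def _load():
        if config.model == "oracle":
            return None
        return load_model(config.model, config.checkpoint)

    model = _stage("load_model", _load)

    # --- tile + predict + aggregate ------------------------------------
    def _count():
        per_plant = {}
        for plant_id, scene in plants:
            grid, tiles = tile_image(scene.image, config.tile_size_px, plant_id)
            if model is None:
                gt_tiles = assign_points_to_tiles(scene.points, grid)
                counts = [gt_tiles[(t.grid_row, t.grid_col)] for t in tiles]
            else:
                counts = [model.predict(t.pixels).count_int for t in tiles]
            per_plant[plant_id] = {
                "true_total": scene.count,
                "tile_counts": [int(c) for c in counts],
                "predicted_total": float(aggregate_plant_count(counts)),
            }
        return per_plant

    per_plant = _stage("predict", _count)

    # --- evaluate -------------------------------------------------------
    def _evaluate():
        if model is None:
            totals = {
                pid: {
                    "ground_truth": float(info["true_total"]),
                    "per_run_totals": [info["predicted_total"]],
                    "mean": info["predicted_total"],
                    "std": 0.0,
                }
                for pid, info in per_plant.items()
            }
        else:
            totals = evaluate_plants(
                [model],
                [(pid, scene.image, scene.count) for pid, scene in plants],
                config.tile_size_px,
            )
        return totals

    totals = _stage("evaluate", _evaluate)

    cfg_dict = dataclasses.asdict(config)
    # hash the scientific configuration only: output/checkpoint paths do
    # not change what is computed
    hashed = {k: v for k, v in cfg_dict.items() if k not in ("out_dir", "checkpoint")}
    cfg_hash = hashlib.sha256(
        json.dumps(hashed, sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest = {
        "config": cfg_dict,
        "config_hash": cfg_hash,
        "seed": config.seed,
        "version": __version__,
        "supervision": {
            "oracle": "ground-truth points",
            "scount": "integer counts",
            "wscount": "class labels only",
            "countseg": "class labels + range-capped counts",
        }[config.model],
    }
    report = {"plants": per_plant, "plant_totals": totals, "config_hash": cfg_hash}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
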