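"""Count-evaluation protocol: per-bin RMSE, run ensembles, regression fits.

Counting models are trained K times (K = 5 in the original protocol)
with different seeds; per-tile errors use the *median* of the K
predictions (lower median for even K), RMSE is reported per count bin as
mean ± std over the K run-level RMSEs, and a least-squares line of
predicted on true counts summarizes calibration. The error sign
convention is ``error = ground truth − prediction``: positive errors
mean under-counting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .annotations import CountBin, bin_count
from .tiling import aggregate_plant_count, tile_image

__all__ = [
    "RunEnsemble",
    "EvalReport",
    "rmse",
    "median_prediction",
    "error_histogram",
    "least_squares_fit",
    "bubble_data",
    "evaluate_model",
    "evaluate_runs",
    "evaluate_plants",
    "write_report",
]


def rmse(ground_truth, predicted) -> float:
    """Root mean squared error between counts (Σ(g−p)²/N, square-rooted)."""
    g = np.asarray(ground_truth, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if g.shape != p.shape:
        raise ValueError(f"length mismatch: {g.shape} vs {p.shape}")
    if g.size == 0:
        raise ValueError("rmse needs at least one pair")
    return float(np.sqrt(np.mean((g - p) ** 2)))


def median_prediction(runs) -> int:
    """Median of the per-run counts; lower median when K is even."""
    values = sorted(int(v) for v in runs)
    if not values:
        raise ValueError("median of an empty prediction list")
    return values[(len(values) - 1) // 2]


def error_histogram(ground_truth, predicted) -> tuple[dict[int, int], float]:
    """Signed integer errors (gt − pred) and the fraction within ±3."""
    g = np.asarray(ground_truth)
    p = np.asarray(predicted)
    if g.shape != p.shape:
        raise ValueError(f"length mismatch: {g.shape} vs {p.shape}")
    errors = np.rint(g - p).astype(int)
    hist: dict[int, int] = {}
    for e in errors:
        hist[int(e)] = hist.get(int(e), 0) + 1
    within = float(np.mean(np.abs(errors) <= 3)) if errors.size else 0.0
    return dict(sorted(hist.items())), within


def least_squares_fit(ground_truth, predicted) -> tuple[float, float, float]:
    """OLS of predicted on ground truth: (slope, intercept, R²)."""
    g = np.asarray(ground_truth, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if g.shape != p.shape or g.size < 2:
        raise ValueError("need >= 2 equal-length pairs")
    if np.unique(g).size < 2:
        raise ValueError("degenerate fit: ground truth is constant")
    fit = stats.linregress(g, p)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def bubble_data(ground_truth, predicted) -> list[tuple[tuple[int, int], int]]:
    """Scatter points with multiplicity, for bubble-plot rendering."""
    pairs: dict[tuple[int, int], int] = {}
    for g, p in zip(ground_truth, predicted):
        key = (int(g), int(p))
        pairs[key] = pairs.get(key, 0) + 1
    return sorted(pairs.items())


@dataclass
class RunEnsemble:
    """Per-tile predictions from K independently trained runs."""

    predictions: dict[str, list[int]]

    def __post_init__(self) -> None:
        ks = {len(v) for v in self.predictions.values()}
        if len(ks) > 1:
            raise ValueError(f"unequal run counts across tiles: {sorted(ks)}")

    @property
    def k(self) -> int:
        return len(next(iter(self.predictions.values()))) if self.predictions else 0

    def medians(self) -> dict[str, int]:
        return {tid: median_prediction(runs) for tid, runs in self.predictions.items()}


@dataclass
class EvalReport:
    rmse_by_bin: dict[str, tuple[float, float]]
    overall_rmse: tuple[float, float]
    error_histogram: dict[int, int]
    fraction_within_3: float
    fit: tuple[float, float, float] | None
    bubbles: list[tuple[tuple[int, int], int]] = field(default_factory=list)
    plant_totals: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rmse_by_bin": {k: list(v) for k, v in self.rmse_by_bin.items()},
            "overall_rmse": list(self.overall_rmse),
            "error_histogram": {str(k): v for k, v in self.error_histogram.items()},
            "fraction_within_3": self.fraction_within_3,
            "fit": list(self.fit) if self.fit else None,
            "bubbles": [[list(pt), m] for pt, m in self.bubbles],
            "plant_totals": self.plant_totals,
        }


def _mean_std(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=np.float64)
    std = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), std


def evaluate_runs(
    ground_truth: dict[str, int],
    ensemble: RunEnsemble,
    subitizing_max: int = 10,
    discard_above: int = 15,
) -> EvalReport:
    """Build the full report from ground truth and K-run predictions.

    Per-bin and overall RMSE are computed per run and reported as
    mean ± sample std over runs; the histogram, ±3 fraction and the
    least-squares fit use the per-tile median predictions. Bins with no
    tiles are omitted rather than reported as NaN.
    """
    tids = sorted(ground_truth)
    missing = [t for t in tids if t not in ensemble.predictions]
    if missing:
        raise ValueError(f"missing predictions for tiles: {missing[:5]}")
    gt = np.array([ground_truth[t] for t in tids])
    runs = np.array([ensemble.predictions[t] for t in tids])  # (n, K)
    k = runs.shape[1]

    bins = np.array(
        [bin_count(int(c), subitizing_max, discard_above).value for c in gt]
    )
    rmse_by_bin: dict[str, tuple[float, float]] = {}
    for name in [b.value for b in CountBin]:
        sel = bins == name
        if not sel.any():
            continue
        per_run = [rmse(gt[sel], runs[sel, j]) for j in range(k)]
        rmse_by_bin[name] = _mean_std(per_run)
    overall = _mean_std([rmse(gt, runs[:, j]) for j in range(k)])

    medians = np.array([median_prediction(runs[i]) for i in range(len(tids))])
    hist, within = error_histogram(gt, medians)
    fit = None
    if np.unique(gt).size >= 2:
        fit = least_squares_fit(gt, medians)
    return EvalReport(
        rmse_by_bin=rmse_by_bin,
        overall_rmse=overall,
        error_histogram=hist,
        fraction_within_3=within,
        fit=fit,
        bubbles=bubble_data(gt, medians),
    )


def _predict_count(model, tile) -> int:
    if callable(model) and not hasattr(model, "predict"):
        return int(model(tile))
    return model.predict(tile).count_int


def evaluate_model(
    models,
    test_set,
    subitizing_max: int = 10,
    discard_above: int = 15,
) -> EvalReport:
    """Evaluate K trained runs of one method on a labeled test set.

    ``models`` is a list of K predictors (objects with ``.predict`` or
    plain callables tile → count); ``test_set`` is a list of examples
    with ``image``/``count``/``tile_id`` attributes.
    """
    if not models:
        raise ValueError("need at least one trained run")
    ground_truth: dict[str, int] = {}
    predictions: dict[str, list[int]] = {}
    for i, ex in enumerate(test_set):
        tid = getattr(ex, "tile_id", "") or f"tile_{i:05d}"
        ground_truth[tid] = int(ex.count_ if hasattr(ex, "count_") else ex.count)
        predictions[tid] = [_predict_count(m, ex.image) for m in models]
    return evaluate_runs(
        ground_truth, RunEnsemble(predictions), subitizing_max, discard_above
    )


def evaluate_plants(
    models,
    plants,
    tile_size_px: int = 500,
) -> dict[str, dict]:
    """End-to-end plant totals: tile each full image, predict per tile,
    sum, and report mean ± std across the K runs.

    ``plants`` is a list of (plant_id, image, true_total).
    """
    totals: dict[str, dict] = {}
    for plant_id, image, true_total in plants:
        _grid, tiles = tile_image(image, tile_size_px, source_id=plant_id)
        per_run = []
        for model in models:
            counts = [_predict_count(model, t.pixels) for t in tiles]
            per_run.append(aggregate_plant_count(counts))
        mean, std = _mean_std(per_run)
        totals[plant_id] = {
            "ground_truth": float(true_total),
            "per_run_totals": [float(v) for v in per_run],
            "mean": mean,
            "std": std,
        }
    return totals


def write_report(report: EvalReport, path: str | Path) -> None:
    """JSON report (stable key order, so identical runs are byte-identical)."""
    Path(path).write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True))
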