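"""Evaluation protocol: RMSE, medians, histograms, fits, run ensembles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from weakcount.evaluation import (
    RunEnsemble,
    bubble_data,
    error_histogram,
    evaluate_model,
    evaluate_plants,
    evaluate_runs,
    least_squares_fit,
    median_prediction,
    rmse,
)
from weakcount.models.common import TrainingExample


def normal_equations_fit(x, y):
    """Closed-form OLS oracle via the normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    a = np.vstack([x, np.ones_like(x)]).T
    slope, intercept = np.linalg.solve(a.T @ a, a.T @ y)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1 - (resid**2).sum() / ss_tot if ss_tot > 0 else 1.0
    return slope, intercept, r2


class TestRmse:
    def test_hand_values(self):
        assert rmse([2, 4], [2, 4]) == 0.0
        assert rmse([0, 3], [1, 5]) == pytest.approx(np.sqrt(2.5))

    def test_errors(self):
        with pytest.raises(ValueError):
            rmse([1], [1, 2])
        with pytest.raises(ValueError):
            rmse([], [])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 30))
            g = rng.integers(0, 15, size=n)
            p = rng.normal(size=n)
            brute = np.sqrt(sum((a - b) ** 2 for a, b in zip(g, p)) / n)
            assert abs(rmse(g, p) - brute) < 1e-9


class TestMedian:
    @pytest.mark.parametrize(
        "runs,expected", [([3, 5, 4, 4, 9], 4), ([7], 7), ([1, 2, 3, 4], 2)]
    )
    def test_median_with_lower_rule(self, runs, expected):
        assert median_prediction(runs) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_prediction([])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 20), min_size=1, max_size=9))
    def test_odd_length_matches_numpy(self, runs):
        if len(runs) % 2 == 1:
            assert median_prediction(runs) == int(np.median(runs))


class TestErrorHistogram:
    def test_identical_vectors(self):
        hist, frac = error_histogram([1, 2, 3], [1, 2, 3])
        assert hist == {0: 3} and frac == 1.0

    def test_single_undercount(self):
        hist, frac = error_histogram([5], [1])
        assert hist == {4: 1} and frac == 0.0

    def test_sign_convention_positive_means_undercounting(self):
        hist, _ = error_histogram([5, 0], [3, 2])
        assert hist == {-2: 1, 2: 1}

    def test_fraction_matches_brute_force(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 40))
            g = rng.integers(0, 15, size=n)
            p = rng.integers(0, 15, size=n)
            _hist, frac = error_histogram(g, p)
            brute = sum(1 for a, b in zip(g, p) if abs(a - b) <= 3) / n
            assert abs(frac - brute) < 1e-12


class TestLeastSquaresFit:
    def test_identity_line(self):
        slope, intercept, r2 = least_squares_fit([0, 1, 2, 3], [0, 1, 2, 3])
        assert (slope, intercept, r2) == pytest.approx((1.0, 0.0, 1.0))

    def test_affine_line(self):
        x = [0, 1, 2, 5]
        slope, intercept, r2 = least_squares_fit(x, [2 * v + 1 for v in x])
        assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_degenerate_constant_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            least_squares_fit([2, 2, 2], [1, 2, 3])

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 40))
            x = rng.integers(0, 15, size=n).astype(float)
            if np.unique(x).size < 2:
                continue
            y = 1.5 * x + rng.normal(size=n)
            got = least_squares_fit(x, y)
            want = normal_equations_fit(x, y)
            assert np.allclose(got, want, atol=1e-9)


class TestEvaluateRuns:
    def _ensemble(self, gt, runs):
        return (
            {f"t{i}": c for i, c in enumerate(gt)},
            RunEnsemble({f"t{i}": list(r) for i, r in enumerate(runs)}),
        )

    def test_perfect_model(self):
        gt = [0, 3, 7, 12]
        truth, ens = self._ensemble(gt, [[c] * 5 for c in gt])
        report = evaluate_runs(truth, ens)
        assert report.overall_rmse == (0.0, 0.0)
        assert all(m == 0.0 for m, _s in report.rmse_by_bin.values())
        assert report.fraction_within_3 == 1.0
        assert report.fit == pytest.approx((1.0, 0.0, 1.0))

    def test_constant_zero_model_hand_rmse(self):
        gt = [0] * 10 + [3] * 10
        truth, ens = self._ensemble(gt, [[0] for _ in gt])
        report = evaluate_runs(truth, ens)
        assert report.overall_rmse[0] == pytest.approx(np.sqrt(90 / 20))
        assert report.overall_rmse[1] == 0.0

    def test_identical_runs_zero_std(self):
        gt = [1, 4, 9]
        truth, ens = self._ensemble(gt, [[2] * 5, [3] * 5, [8] * 5])
        report = evaluate_runs(truth, ens)
        assert report.overall_rmse[1] == 0.0
        for _m, s in report.rmse_by_bin.values():
            assert s == 0.0

    def test_empty_bins_absent_not_nan(self):
        truth, ens = self._ensemble([1, 2], [[1], [2]])
        report = evaluate_runs(truth, ens)
        assert set(report.rmse_by_bin) == {"b1_5"}

    def test_overall_rmse_between_bin_extremes(self, rng):
        gt = list(rng.integers(0, 15, size=60))
        runs = [[int(max(0, c + rng.integers(-3, 4)))] for c in gt]
        truth, ens = self._ensemble(gt, runs)
        report = evaluate_runs(truth, ens)
        per_bin = [m for m, _ in report.rmse_by_bin.values()]
        assert min(per_bin) - 1e-12 <= report.overall_rmse[0] <= max(per_bin) + 1e-12

    def test_unequal_run_counts_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            RunEnsemble({"a": [1, 2], "b": [1]})

    def test_bubble_multiplicities(self):
        data = bubble_data([1, 1, 2], [1, 1, 3])
        assert data == [((1, 1), 2), ((2, 3), 1)]


class TestEvaluatePlants:
    def test_oracle_model_conserves_totals(self):
        import dataclasses

        from weakcount.synthetic import benchmark_config, generate_scene
        from weakcount.tiling import TileGrid, assign_points_to_tiles

        cfg = dataclasses.replace(
            benchmark_config(seed=17),
            image_height_px=128,
            image_width_px=128,
            count_range=(6, 12),
        )
        scene = generate_scene(cfg)

        class Oracle:
            """Counts ground-truth points inside each 64px tile window."""

            def __init__(self, scene):
                grid = TileGrid.for_image(128, 128, 64)
                self.lookup = assign_points_to_tiles(scene.points, grid)
                self.calls = 0

            def __call__(self, tile):
                r, c = divmod(self.calls, 2)
                self.calls += 1
                return self.lookup[(r, c)]

        oracle = Oracle(scene)
        totals = evaluate_plants([oracle], [("p0", scene.image, scene.count)], 64)
        assert totals["p0"]["per_run_totals"] == [scene.count]
        assert totals["p0"]["std"] == 0.0

    def test_constant_zero_model(self):
        img = np.zeros((128, 128, 3))
        totals = evaluate_plants(
            [lambda tile: 0, lambda tile: 0], [("p", img, 5)], 64
        )
        assert totals["p"]["mean"] == 0.0 and totals["p"]["std"] == 0.0


def test_evaluate_model_with_callable_predictors():
    tiles = [
        TrainingExample(image_=np.zeros((8, 8, 3)), count_=c, tile_id=f"t{i}")
        for i, c in enumerate([0, 2, 2, 4])
    ]
    report = evaluate_model([lambda t: 2, lambda t: 2, lambda t: 2], tiles)
    assert report.overall_rmse[0] == pytest.approx(np.sqrt((4 + 0 + 0 + 4) / 4))
    assert report.overall_rmse[1] == 0.0
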