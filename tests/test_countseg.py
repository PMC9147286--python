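"""CountSeg: branch split, the three losses, pseudo ground truth, peaks."""

import logging

import numpy as np
import pytest

from weakcount.benchmark import heldout_rmse
from weakcount.models import (
    CountSegConfig,
    CountSegLoss,
    DensityMap,
    build_countseg,
    loss_class,
    loss_global,
    loss_spatial,
    make_pseudo_ground_truth,
    peak_instances,
    train_countseg,
)
from weakcount.models.common import CountPrediction, SupervisionLog
from weakcount.models.countseg import countseg_forward


def brute_force_local_maxima(arr, radius):
    """Oracle: a cell is a peak iff it is >= every cell within the radius."""
    h, w = arr.shape
    peaks = []
    for r in range(h):
        for c in range(w):
            window = arr[
                max(0, r - radius) : r + radius + 1, max(0, c - radius) : c + radius + 1
            ]
            if arr[r, c] >= window.max():
                peaks.append((r, c))
    return peaks


def bumps_map(centers, shape=(16, 16), sigma=1.2):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    out = np.zeros(shape)
    for (r, c) in centers:
        out += np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma**2))
    return out


class TestForward:
    def test_channels_split_half_half(self):
        model = build_countseg(CountSegConfig(shared_channels=60, seed=0))
        assert model.half == 30
        assert model.cls_conv.cin == 30 and model.den_conv.cin == 30

    def test_odd_channel_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            CountSegConfig(shared_channels=61)

    def test_zero_tile_finite_and_nonnegative_density(self):
        model = build_countseg(CountSegConfig(seed=0))
        score, conf, density = countseg_forward(model, np.zeros((64, 64, 3)))
        assert np.isfinite(score) and np.isfinite(conf).all()
        assert (density.values >= 0).all() and density.global_count >= 0

    def test_evaluation_mode_deterministic(self, countseg_model, bench):
        tile = bench.test[0].image_
        a = countseg_forward(countseg_model, tile)
        b = countseg_forward(countseg_model, tile)
        assert a[0] == b[0]
        assert np.array_equal(a[2].values, b[2].values)

    def test_class_score_is_spatial_max_of_confidence(self, countseg_model, bench):
        score, conf, _ = countseg_forward(countseg_model, bench.test[0].image_)
        assert score == pytest.approx(conf.max())


class TestLossClass:
    def test_confident_correct_is_exactly_zero(self):
        assert loss_class(1.0, "present", score_is_probability=True) == 0.0
        assert loss_class(0.0, "absent", score_is_probability=True) == 0.0

    def test_half_probability_is_ln2(self):
        for label in ("present", "absent"):
            assert loss_class(0.5, label, score_is_probability=True) == pytest.approx(
                np.log(2)
            )

    def test_absent_closed_form(self):
        for p in (0.1, 0.25, 0.9):
            assert loss_class(p, "absent", score_is_probability=True) == pytest.approx(
                -np.log(1 - p)
            )

    def test_logit_mode_matches_probability_mode(self):
        for logit in (-2.0, 0.0, 1.5):
            p = 1 / (1 + np.exp(-logit))
            assert loss_class(logit, "present") == pytest.approx(
                loss_class(p, "present", score_is_probability=True)
            )


class TestLossGlobal:
    def test_exact_match_is_zero(self):
        assert loss_global(DensityMap(np.full((2, 2), 1.0)), 4) == 0.0

    def test_squared_error_inside_range(self):
        assert loss_global(DensityMap(np.full((2, 2), 0.5)), 4) == pytest.approx(4.0)

    def test_hinge_inactive_beyond_range(self):
        # count 13 beyond subitizing max 10: density sum 12 >= 11 satisfies ILC
        assert loss_global(DensityMap(np.full((2, 2), 3.0)), 13, subitizing_max=10) == 0.0

    def test_hinge_penalizes_underestimation_only(self):
        low = DensityMap(np.full((2, 2), 2.0))  # sum 8 < 11
        assert loss_global(low, 13, subitizing_max=10) == pytest.approx(9.0)

    def test_dnc_tile_rejected(self):
        with pytest.raises(ValueError, match="dnc"):
            loss_global(DensityMap(np.zeros((2, 2))), 16)


class TestPseudoGroundTruth:
    def test_flat_map_zero_count_empty(self):
        assert not make_pseudo_ground_truth(np.ones((8, 8)), 0).any()

    def test_three_bumps_found_at_apices(self):
        centers = [(3, 3), (3, 12), (12, 7)]
        conf = bumps_map(centers)
        mask = make_pseudo_ground_truth(conf, 3, neighborhood_px=3)
        assert mask.sum() == 3
        assert all(mask[r, c] for r, c in centers)
        # agrees with the brute-force local-maxima oracle
        oracle = set(brute_force_local_maxima(conf, 3))
        assert set(map(tuple, np.argwhere(mask))) <= oracle

    def test_count_above_maxima_marks_all_and_warns(self, caplog):
        import weakcount.models.countseg as cs

        cs._peak_shortfalls_seen.clear()  # the warning is once-per-shortfall
        conf = bumps_map([(4, 4), (10, 10)])
        with caplog.at_level(logging.WARNING, logger="weakcount.models.countseg"):
            mask = make_pseudo_ground_truth(conf, 5, neighborhood_px=3)
        assert mask.sum() < 5
        assert any("maxima" in rec.message for rec in caplog.records)


class TestLossSpatial:
    def test_perfect_localization_exactly_zero(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 2] = True
        density = mask.astype(float)
        assert loss_spatial(density, mask) == 0.0

    def test_uniform_density_penalized(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        assert loss_spatial(np.full((4, 4), 0.5), mask) > 0.0

    def test_moving_mass_toward_peak_decreases_loss(self):
        # peak at (1,1), a decoy cell at (3,3); shifting mass from the
        # decoy to the peak must reduce the loss (finite-difference check)
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = True
        d = np.full((4, 4), 0.2)
        d[0, 0] = 0.0
        d[1, 1] = 0.9
        d[3, 3] = 0.5
        before = loss_spatial(d, mask)
        assert before > 0.0
        d2 = d.copy()
        d2[1, 1] += 0.2
        d2[3, 3] -= 0.2
        assert loss_spatial(d2, mask) < before

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            loss_spatial(np.zeros((4, 4)), np.zeros((3, 3), bool))


class TestPeakInstances:
    def test_separated_bumps_recovered(self):
        centers = [(3, 3), (3, 12), (12, 7)]
        density = DensityMap(bumps_map(centers), stride_px=1)
        peaks = peak_instances(density, threshold=0.5, neighborhood_px=3)
        assert len(peaks) == 3
        for (r, c) in centers:
            assert any(abs(x - c) <= 1 and abs(y - r) <= 1 for x, y in peaks)

    def test_stride_maps_to_image_coordinates(self):
        density = DensityMap(bumps_map([(4, 4)]), stride_px=8)
        ((x, y),) = peak_instances(density, threshold=0.5)
        assert x == pytest.approx((4 + 0.5) * 8 - 0.5)
        assert y == pytest.approx((4 + 0.5) * 8 - 0.5)

    def test_all_zero_map_empty(self):
        assert peak_instances(DensityMap(np.zeros((8, 8))), 0.0) == []

    def test_threshold_monotonicity(self):
        density = DensityMap(bumps_map([(3, 3), (10, 10), (3, 12)]))
        n_prev = None
        for thr in (0.1, 0.4, 0.8, 1.2):
            n = len(peak_instances(density, thr))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n


class TestTraining:
    def test_total_is_exact_sum(self):
        loss = CountSegLoss(l_class=0.1, l_spatial=0.2, l_global=0.7)
        assert loss.total == 0.1 + 0.2 + 0.7

    def test_ilc_contract_no_points_capped_counts(self, bench):
        audit = SupervisionLog()
        from weakcount.benchmark import make_benchmark

        data = make_benchmark(seed=4, audit=audit)
        cfg = CountSegConfig(epochs=1, seed=0)
        train_countseg(build_countseg(cfg), data.train[:20], cfg)
        assert audit.accessed("class_label")
        assert audit.accessed("ilc_count")
        assert not audit.accessed("points")
        assert not audit.accessed("count")
        assert all(c <= cfg.subitizing_max + 1 for c in audit.counts_seen)

    def test_prediction_is_density_sum_rounded(self, countseg_model, bench):
        tile = bench.test[0].image_
        _, _, density = countseg_forward(countseg_model, tile)
        pred = countseg_model.predict(tile)
        assert pred.count_real == pytest.approx(density.global_count, rel=1e-6)
        assert CountPrediction(7.4).count_int == 7

    def test_heldout_rmse_on_easy_benchmark(self, countseg_model, bench):
        assert heldout_rmse(countseg_model, bench) <= 1.5

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_countseg(build_countseg(CountSegConfig(seed=0)), [])

    def test_save_load_round_trip(self, countseg_model, bench, tmp_path):
        from weakcount.models.countseg import CountSegModel

        path = tmp_path / "cs.npz"
        countseg_model.save(path)
        reloaded = CountSegModel.load(path)
        tile = bench.test[0].image_
        assert reloaded.predict(tile).count_real == pytest.approx(
            countseg_model.predict(tile).count_real
        )
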