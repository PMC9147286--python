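"""WS-Count: multi-scale split, consistency losses, weak-supervision purity."""

import numpy as np
import pytest

from weakcount.benchmark import heldout_rmse, make_benchmark
from weakcount.models import (
    BranchOutputs,
    WSCountConfig,
    WSCountLoss,
    build_wscount,
    loss_pac_consistency,
    loss_spatial_consistency,
    split_multiscale,
    train_wscount,
)
from weakcount.models.common import SupervisionLog
from weakcount.models.wscount import pac_accuracy


def outputs(counts, probs):
    return BranchOutputs(np.asarray(counts, float), np.asarray(probs, float))


def consistent(counts=None, probs=None):
    c = np.zeros(21) if counts is None else counts
    p = np.zeros(21) if probs is None else probs
    return outputs(c, p)


class TestSplitMultiscale:
    @pytest.mark.parametrize("side,expected", [(500, (500, 250, 125)), (64, (64, 32, 16))])
    def test_scale_sides(self, side, expected):
        tile = np.zeros((side, side, 3))
        ms = split_multiscale(tile)
        assert len(ms.patches) == 21
        assert ms.full[0].shape[0] == expected[0]
        assert all(q.shape[0] == expected[1] for q in ms.quarters)
        assert all(s.shape[0] == expected[2] for s in ms.sixteenths)

    def test_quarters_reassemble_bit_exactly(self, rng):
        tile = rng.random((64, 64, 3))
        ms = split_multiscale(tile)
        top = np.concatenate(ms.quarters[:2], axis=1)
        bot = np.concatenate(ms.quarters[2:], axis=1)
        assert np.array_equal(np.concatenate([top, bot], axis=0), tile)

    def test_sixteenths_partition_exactly(self, rng):
        tile = rng.random((64, 64, 3))
        ms = split_multiscale(tile)
        rows = [
            np.concatenate(ms.sixteenths[4 * r : 4 * r + 4], axis=1) for r in range(4)
        ]
        assert np.array_equal(np.concatenate(rows, axis=0), tile)

    def test_indivisible_side_rejected(self):
        with pytest.raises(ValueError, match="divisible by 4"):
            split_multiscale(np.zeros((30, 30, 3)))


class TestConsistencyLosses:
    def test_consistent_absence_is_zero(self):
        assert loss_pac_consistency(consistent()) == 0.0

    def test_consistent_presence_is_zero(self):
        out = outputs(np.full(21, 2.0), np.ones(21))
        assert loss_pac_consistency(out) == 0.0

    def test_single_branch_contributions(self):
        # p=1 with c=0 on one branch -> 1/21; p=0 with c=2 -> 2/21
        p = np.zeros(21)
        p[0] = 1.0
        assert loss_pac_consistency(outputs(np.zeros(21), p)) == pytest.approx(1 / 21)
        c = np.zeros(21)
        c[3] = 2.0
        assert loss_pac_consistency(outputs(c, np.zeros(21))) == pytest.approx(2 / 21)

    def test_probability_out_of_range_rejected(self):
        bad = consistent()
        bad.presence_probs[0] = 1.5
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            loss_pac_consistency(bad)

    def test_spatial_consistency_zero_and_hand_value(self):
        c = np.zeros(21)
        c[0] = 5.0
        c[1:5] = 5 / 4
        c[5:21] = 5 / 16
        assert loss_spatial_consistency(outputs(c, np.zeros(21))) == pytest.approx(0.0)
        # C1=4, C4=2, C16=2 -> |4-2| + |4-2| + |2-2| = 4
        c = np.zeros(21)
        c[0] = 4.0
        c[1] = 2.0
        c[5] = 2.0
        assert loss_spatial_consistency(outputs(c, np.zeros(21))) == pytest.approx(4.0)

    def test_spatial_consistency_positively_homogeneous(self, rng):
        c = np.abs(rng.normal(size=21))
        base = loss_spatial_consistency(outputs(c, np.zeros(21)))
        for lam in (0.5, 2.0, 7.0):
            scaled = loss_spatial_consistency(outputs(lam * c, np.zeros(21)))
            assert scaled == pytest.approx(lam * base, rel=1e-9)

    def test_total_is_exact_sum(self):
        loss = WSCountLoss(l_pac_c=0.25, l_sp_c=1.5)
        assert loss.total == 0.25 + 1.5

    def test_negative_counts_rejected_by_branch_outputs(self):
        with pytest.raises(ValueError, match="nonnegative"):
            outputs(np.full(21, -1.0), np.zeros(21))


class TestWeakTraining:
    def test_count_supervision_rejected(self):
        cfg = WSCountConfig(seed=0)
        model = build_wscount(cfg)
        tiles = [np.zeros((64, 64, 3))]
        with pytest.raises(TypeError, match="never counts"):
            train_wscount(model, [(tiles[0], 3)], cfg)

    def test_training_consumes_only_class_labels(self):
        audit = SupervisionLog()
        data = make_benchmark(seed=3, audit=audit)
        cfg = WSCountConfig(pac_epochs=1, count_epochs=1, seed=0)
        train_wscount(build_wscount(cfg), data.train[:20], cfg)
        assert audit.accessed("class_label")
        assert not audit.accessed("count")
        assert not audit.accessed("ilc_count")
        assert not audit.accessed("points")

    def test_pac_accuracy_on_easy_benchmark(self, wscount_model, bench):
        assert pac_accuracy(wscount_model, bench.test) >= 0.95

    def test_heldout_rmse_within_weak_tolerance(self, wscount_model, bench):
        assert heldout_rmse(wscount_model, bench) <= 2.0

    def test_spatial_consistency_decreases_over_training(self, bench):
        # average over seeds: L_SP-C at the end below its starting level
        drops = []
        for seed in range(3):
            cfg = WSCountConfig(
                pac_epochs=2, count_epochs=4, batch_size=16, learning_rate=3e-3, seed=seed
            )
            _m, trace = train_wscount(build_wscount(cfg), bench.train[:60], cfg)
            drops.append(trace[-1].l_sp_c - trace[0].l_sp_c)
        assert np.mean(drops) < 0

    def test_prediction_contracts(self, wscount_model, bench):
        tile = bench.test[0].image_
        pred = wscount_model.predict(tile)
        assert pred.count_int >= 0
        # evaluation-mode determinism, and scale-1 branch is the default
        out = wscount_model.forward_branches(tile)
        assert pred.count_real == pytest.approx(max(0.0, out.counts[0]))
        out2 = wscount_model.forward_branches(tile)
        assert np.array_equal(out.counts, out2.counts)
        assert np.array_equal(out.presence_probs, out2.presence_probs)
        assert np.all(out.presence_probs >= 0) and np.all(out.presence_probs <= 1)

    def test_empty_tile_predicts_zero(self, wscount_model):
        from weakcount.synthetic import benchmark_config, generate_scene
        import dataclasses

        empty = generate_scene(
            dataclasses.replace(benchmark_config(seed=77), count_range=(0, 0))
        )
        assert wscount_model.predict(empty.image).count_int == 0

    def test_save_load_round_trip(self, wscount_model, bench, tmp_path):
        from weakcount.models.wscount import WSCountModel

        path = tmp_path / "ws.npz"
        wscount_model.save(path)
        reloaded = WSCountModel.load(path)
        tile = bench.test[0].image_
        assert reloaded.predict(tile).count_real == pytest.approx(
            wscount_model.predict(tile).count_real
        )
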