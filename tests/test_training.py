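"""Schedules, epoch sampling, augmentation and the training loop."""

import numpy as np
import pytest

from cellseg.flow import masks_to_flows
from cellseg.network import NetConfig
from cellseg.synthetic import SceneConfig, generate_scene
from cellseg.training import (
    AugmentConfig,
    TrainConfig,
    TrainingError,
    TransformParams,
    apply_transform,
    draw_transform,
    lr_schedule,
    make_epoch,
    train_model,
)


class TestLrSchedule:
    def test_offline_schedule_values(self):
        cfg = TrainConfig.offline()
        # linear warmup over the first ten epochs
        assert lr_schedule(cfg, 0) == pytest.approx(0.01)
        assert lr_schedule(cfg, 4) == pytest.approx(0.05)
        assert lr_schedule(cfg, 9) == pytest.approx(0.1)
        # plateau at the peak
        assert lr_schedule(cfg, 100) == pytest.approx(0.1)
        assert lr_schedule(cfg, 250) == pytest.approx(0.1)
        # halving every 5 epochs after epoch 250
        assert lr_schedule(cfg, 251) == pytest.approx(0.05)
        assert lr_schedule(cfg, 252) == pytest.approx(0.05)
        assert lr_schedule(cfg, 256) == pytest.approx(0.025)
        assert lr_schedule(cfg, 299) == pytest.approx(0.1 * 0.5**10)

    def test_online_never_anneals(self):
        cfg = TrainConfig.online()
        assert cfg.epochs == 100
        assert lr_schedule(cfg, 99) == pytest.approx(0.1)
        assert all(
            lr_schedule(cfg, e) == pytest.approx(0.1) for e in range(10, 100)
        )

    def test_generalist_schedule(self):
        cfg = TrainConfig.generalist()
        assert (cfg.epochs, cfg.weight_decay, cfg.peak_lr) == (500, 1e-5, 0.2)
        assert lr_schedule(cfg, 9) == pytest.approx(0.2)
        assert lr_schedule(cfg, 400) == pytest.approx(0.2)
        assert lr_schedule(cfg, 401) == pytest.approx(0.1)
        assert lr_schedule(cfg, 411) == pytest.approx(0.05)

    def test_epoch_out_of_range(self):
        cfg = TrainConfig.online()
        with pytest.raises(IndexError):
            lr_schedule(cfg, 100)
        with pytest.raises(IndexError):
            lr_schedule(cfg, -1)

    def test_offline_defaults_match_protocol(self):
        cfg = TrainConfig.offline()
        assert cfg.epochs == 300
        assert cfg.batch_size == 8
        assert cfg.weight_decay == pytest.approx(1e-4)
        assert cfg.peak_lr == pytest.approx(0.1)


class TestMakeEpoch:
    def test_small_set_resampled_to_minimum(self, rng):
        cfg = TrainConfig.online(seed=0)
        batches = make_epoch(3, cfg, rng)
        assert len(batches) == 1
        assert batches[0].size == 8
        assert set(batches[0]) <= {0, 1, 2}

    def test_large_set_batched(self, rng):
        cfg = TrainConfig.online()
        batches = make_epoch(16, cfg, rng)
        assert [b.size for b in batches] == [8, 8]
        assert sorted(np.concatenate(batches)) == list(range(16))

    def test_deterministic_under_seed(self):
        cfg = TrainConfig.online()
        a = make_epoch(5, cfg, np.random.default_rng(7))
        b = make_epoch(5, cfg, np.random.default_rng(7))
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_weighted_sampling_respects_weights(self, rng):
        cfg = TrainConfig.online()
        w = np.array([1.0, 0.0, 0.0])
        batches = make_epoch(3, cfg, rng, weights=w)
        assert np.all(np.concatenate(batches) == 0)

    def test_empty_set_raises(self, rng):
        with pytest.raises(ValueError):
            make_epoch(0, TrainConfig.online(), rng)


class TestAugment:
    @pytest.fixture()
    def sample(self):
        scene = generate_scene(
            SceneConfig(canvas=(64, 64), n_cells=6, diameter_mean=12, seed=3)
        )
        return scene.pixels, scene.labels, masks_to_flows(scene.labels)

    def test_identity_transform_is_noop(self, sample):
        pix, lab, ft = sample
        p2, l2, f2 = apply_transform(pix, lab, ft, TransformParams())
        assert np.allclose(p2, pix)
        assert np.array_equal(l2, lab)
        assert np.allclose(f2.flow_y, ft.flow_y, atol=1e-6)

    @pytest.mark.parametrize("angle", [90, 180, 270])
    def test_exact_rotations_match_recomputed_flows(self, sample, angle):
        """Rotated flow vectors equal flows recomputed from rotated labels."""
        pix, lab, ft = sample
        _, l2, f2 = apply_transform(pix, lab, ft, TransformParams(angle=angle))
        ref = masks_to_flows(l2)
        inside = l2 > 0
        assert np.abs(f2.flow_y - ref.flow_y)[inside].max() < 1e-5
        assert np.abs(f2.flow_x - ref.flow_x)[inside].max() < 1e-5

    def test_horizontal_flip_negates_flow_x(self, sample):
        pix, lab, ft = sample
        _, _, f2 = apply_transform(pix, lab, ft, TransformParams(flip_h=True))
        assert np.allclose(f2.flow_x, -ft.flow_x[:, ::-1], atol=1e-6)
        assert np.allclose(f2.flow_y, ft.flow_y[:, ::-1], atol=1e-6)

    def test_arbitrary_rotation_keeps_flows_pointing_at_centers(self, sample):
        from scipy import ndimage

        pix, lab, ft = sample
        _, l2, f2 = apply_transform(pix, lab, ft, TransformParams(angle=37.0))
        ref = masks_to_flows(l2)
        interior = ndimage.binary_erosion(l2 > 0, iterations=3)
        cos = (f2.flow_y * ref.flow_y + f2.flow_x * ref.flow_x)[interior]
        assert cos.mean() > 0.85

    def test_crop_pads_small_images(self, sample):
        pix, lab, ft = sample
        p2, l2, f2 = apply_transform(
            pix, lab, ft, TransformParams(crop=96, crop_frac=(0.0, 0.0))
        )
        assert p2.shape[-2:] == (96, 96) and l2.shape == (96, 96)

    def test_draw_transform_deterministic(self):
        cfg = AugmentConfig()
        a = draw_transform(cfg, np.random.default_rng(5))
        b = draw_transform(cfg, np.random.default_rng(5))
        assert a == b

    def test_scale_range_validated(self):
        with pytest.raises(ValueError):
            AugmentConfig(scale_range=(0.3, 1.0))


class TestTrainModel:
    def test_loss_decreases_and_log_complete(self):
        scenes = [
            generate_scene(
                SceneConfig(canvas=(48, 48), n_cells=5, diameter_mean=12,
                            seed=s)
            )
            for s in range(2)
        ]
        cfg = TrainConfig.online(epochs=30, seed=0)
        res = train_model(
            "scratch", scenes, cfg,
            net_config=NetConfig(n_levels=2, base_channels=8, seed=0),
        )
        assert list(res.log.columns) == ["epoch", "lr", "loss"]
        assert len(res.log) == 30
        assert res.log.loss.iloc[-5:].mean() < res.log.loss.iloc[0]

    def test_scratch_requires_net_config(self):
        scene = generate_scene(SceneConfig(canvas=(48, 48), n_cells=5, seed=0))
        with pytest.raises(ValueError):
            train_model("scratch", [scene], TrainConfig.online(epochs=10))

    def test_loss_invariant_to_roi_id_permutation(self):
        """Permuting label ids leaves the training loss unchanged."""
        scene = generate_scene(
            SceneConfig(canvas=(48, 48), n_cells=5, diameter_mean=12, seed=1)
        )
        permuted = scene.labels.copy()
        ids = np.unique(permuted)
        ids = ids[ids > 0]
        mapping = dict(zip(ids, np.roll(ids, 1)))
        relabeled = np.zeros_like(permuted)
        for old, new in mapping.items():
            relabeled[permuted == old] = new
        cfg = TrainConfig.online(epochs=12, seed=0)
        net_cfg = NetConfig(n_levels=2, base_channels=8, seed=0)
        res_a = train_model("scratch", [scene], cfg, net_config=net_cfg)
        res_b = train_model(
            "scratch", [scene.with_labels(relabeled)], cfg, net_config=net_cfg
        )
        assert np.allclose(res_a.log.loss, res_b.log.loss, atol=1e-5)

    def test_finetune_does_not_mutate_init(self, pretrained_domain_a):
        from conftest import domain_scene

        before = {k: v.copy() for k, v in pretrained_domain_a.state_arrays().items()}
        train_model(
            pretrained_domain_a,
            [domain_scene(77, "B")],
            TrainConfig.online(epochs=12, seed=0),
        )
        after = pretrained_domain_a.state_arrays()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_large_learning_rate_trains_without_divergence(self):
        """Peak LR 0.1 on a tiny image set completes the online schedule."""
        scenes = [
            generate_scene(
                SceneConfig(canvas=(48, 48), n_cells=5, diameter_mean=12,
                            seed=s)
            )
            for s in range(3)
        ]
        cfg = TrainConfig.online(epochs=40, seed=1)
        assert cfg.peak_lr == pytest.approx(0.1)
        res = train_model(
            "scratch", scenes, cfg,
            net_config=NetConfig(n_levels=2, base_channels=8, seed=1),
        )
        assert np.isfinite(res.log.loss).all()
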