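"""Flow-field construction, mask reconstruction, QC and diameter handling."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from cellseg.dataio import LabeledImage
from cellseg.evaluation import iou_matrix, match_masks
from cellseg.flow import (
    FlowTarget,
    QcConfig,
    estimate_diameter,
    flow_error,
    follow_flows,
    masks_to_flows,
    remove_bad_flow_masks,
    resize_for_diameter,
    resize_labels_back,
)
from cellseg.synthetic import SceneConfig, generate_scene


def disk_map(centers_radii, shape=(64, 64)):
    labels = np.zeros(shape, np.int32)
    for i, (cy, cx, r) in enumerate(centers_radii, start=1):
        rr, cc = draw_disk((cy, cx), r, shape=shape)
        labels[rr, cc] = i
    return labels


def roundtrip_iou(labels):
    """Mean matched per-ROI IoU of masks_to_flows -> follow_flows."""
    rec = follow_flows(masks_to_flows(labels))
    ious, pi, ti = iou_matrix(rec, labels)
    m = match_masks(ious, 0.5, pi, ti) if ious.size else None
    vals = [iou for _, _, iou in m.pairs] if m else []
    vals += [0.0] * (m.fn if m else len(np.unique(labels)) - 1)
    return float(np.mean(vals)) if vals else 1.0


class TestMasksToFlows:
    def test_flow_magnitudes_bounded_and_zero_outside(self):
        labels = disk_map([(20, 20, 8), (45, 45, 10)])
        ft = masks_to_flows(labels)
        mag = np.hypot(ft.flow_y, ft.flow_x)
        assert np.all(mag <= 1 + 1e-6)
        assert np.all(mag[labels == 0] == 0)
        assert np.array_equal(ft.inside_prob, (labels > 0).astype(np.float32))

    def test_disk_center_has_near_zero_flow(self):
        labels = disk_map([(32, 32, 10)])
        ft = masks_to_flows(labels)
        assert np.hypot(ft.flow_y, ft.flow_x)[32, 32] < 0.2

    def test_empty_map_gives_zero_target(self):
        ft = masks_to_flows(np.zeros((16, 16), np.int32))
        assert ft.flow_y.sum() == 0 and ft.inside_prob.sum() == 0

    def test_bar_flows_point_to_middle(self):
        """1-D bar of length 9: flows point inward, sign flip at middle."""
        labels = np.zeros((5, 13), np.int32)
        labels[2, 2:11] = 1  # columns 2..10, middle at column 6
        ft = masks_to_flows(labels)
        assert np.all(ft.flow_x[2, 2:6] > 0)  # left half points right
        assert np.all(ft.flow_x[2, 7:11] < 0)  # right half points left
        assert abs(ft.flow_x[2, 6]) < 0.2


class TestFollowFlows:
    def test_roundtrip_two_disks(self):
        labels = disk_map([(20, 20, 9), (44, 44, 9)])
        rec = follow_flows(masks_to_flows(labels))
        ious, pi, ti = iou_matrix(rec, labels)
        m = match_masks(ious, 0.5, pi, ti)
        assert m.tp == 2
        assert all(iou >= 0.9 for _, _, iou in m.pairs)

    def test_all_zero_probability_gives_empty_map(self):
        z = np.zeros((32, 32), np.float32)
        assert follow_flows(FlowTarget(z, z, z)).max() == 0

    def test_uniform_rightward_flow_single_sink(self):
        """All trajectories exit to the clamped right edge -> one ROI."""
        H = W = 32
        ft = FlowTarget(
            flow_y=np.zeros((H, W), np.float32),
            flow_x=np.ones((H, W), np.float32),
            inside_prob=np.ones((H, W), np.float32),
        )
        rec = follow_flows(ft, n_steps=2 * W)
        assert rec.max() == 1
        assert np.all(rec == 1)

    def test_nonfinite_flow_raises(self):
        z = np.ones((8, 8), np.float32)
        bad = z.copy()
        bad[2, 2] = np.nan
        with pytest.raises(FloatingPointError):
            follow_flows(FlowTarget(bad, z, z))

    def test_small_rois_discarded(self):
        labels = disk_map([(16, 16, 1.5)], shape=(32, 32))  # ~7 px < 15
        rec = follow_flows(masks_to_flows(labels), min_roi_size=15)
        assert rec.max() == 0

    def test_mirror_equivariance(self):
        labels = disk_map([(20, 24, 8), (44, 40, 9)])
        ft = masks_to_flows(labels)
        rec = follow_flows(ft)
        flipped = FlowTarget(
            flow_y=-ft.flow_y[::-1, ::-1],
            flow_x=-ft.flow_x[::-1, ::-1],
            inside_prob=ft.inside_prob[::-1, ::-1],
        )
        rec_f = follow_flows(flipped)
        ious, _, _ = iou_matrix(rec_f, rec[::-1, ::-1])
        assert match_masks(ious, 0.9).tp == 2


class TestRoundtripProperty:
    def test_mean_roi_iou_on_random_scenes(self):
        """masks_to_flows -> follow_flows round trip on seeded scenes."""
        vals = []
        for seed in range(10):
            scene = generate_scene(
                SceneConfig(canvas=(80, 80), n_cells=8, diameter_mean=12,
                            seed=seed)
            )
            vals.append(roundtrip_iou(scene.labels))
        assert float(np.mean(vals)) >= 0.9


class TestFlowError:
    def test_self_consistent_flows_near_zero(self):
        labels = disk_map([(20, 20, 8), (44, 44, 9)])
        ft = masks_to_flows(labels)
        errs = flow_error(ft, labels)
        assert all(e < 1e-6 for e in errs.values())

    def test_noise_flows_exceed_threshold(self, rng):
        labels = disk_map([(20, 20, 8), (44, 44, 9)])
        theta = rng.uniform(0, 2 * np.pi, labels.shape)
        noise = FlowTarget(
            flow_y=np.sin(theta).astype(np.float32),
            flow_x=np.cos(theta).astype(np.float32),
            inside_prob=(labels > 0).astype(np.float32),
        )
        errs = flow_error(noise, labels)
        assert all(e > 0.4 for e in errs.values())

    def test_qc_removes_only_bad_rois(self, rng):
        labels = disk_map([(20, 20, 8), (44, 44, 9)])
        ft = masks_to_flows(labels)
        # corrupt the flows inside ROI 2 only
        bad = FlowTarget(ft.flow_y.copy(), ft.flow_x.copy(), ft.inside_prob)
        m2 = labels == 2
        theta = rng.uniform(0, 2 * np.pi, int(m2.sum()))
        bad.flow_y[m2] = np.sin(theta)
        bad.flow_x[m2] = np.cos(theta)
        out = remove_bad_flow_masks(bad, labels, QcConfig())
        assert np.unique(out).tolist() == [0, 1]
        assert QcConfig().flow_error_threshold == 0.4

    def test_shape_mismatch_raises(self):
        ft = masks_to_flows(np.zeros((8, 8), np.int32))
        with pytest.raises(ValueError):
            flow_error(ft, np.zeros((9, 8), np.int32))


class TestDiameter:
    def test_single_disk_closed_form(self):
        labels = disk_map([(32, 32, 10)])
        area = np.sum(labels == 1)
        assert estimate_diameter(labels) == pytest.approx(
            2 * np.sqrt(area / np.pi)
        )
        assert estimate_diameter(labels) == pytest.approx(20, rel=0.06)

    def test_mean_of_two_disks(self):
        labels = disk_map([(20, 20, 5), (44, 44, 15)])
        d1 = 2 * np.sqrt(np.sum(labels == 1) / np.pi)
        d2 = 2 * np.sqrt(np.sum(labels == 2) / np.pi)
        assert estimate_diameter(labels) == pytest.approx((d1 + d2) / 2)

    def test_empty_map_raises(self):
        with pytest.raises(ValueError):
            estimate_diameter(np.zeros((8, 8), np.int32))


class TestResizeForDiameter:
    def _img(self, labels):
        return LabeledImage(
            pixels=labels.astype(np.float32), labels=labels
        )

    def test_identity_when_diameters_match(self):
        labels = disk_map([(20, 20, 6)], shape=(48, 48))
        out = resize_for_diameter(self._img(labels), 12.0, 12.0)
        assert out.spatial_shape == (48, 48)
        assert np.array_equal(out.labels, labels)

    def test_upsampling_scales_areas(self):
        labels = disk_map([(20, 20, 6)], shape=(48, 48))
        out = resize_for_diameter(self._img(labels), 15.0, 30.0)
        assert out.spatial_shape == (96, 96)
        ratio = np.sum(out.labels == 1) / np.sum(labels == 1)
        assert ratio == pytest.approx(4.0, rel=0.1)

    def test_out_of_range_factor_raises(self):
        labels = disk_map([(20, 20, 6)], shape=(48, 48))
        with pytest.raises(ValueError):
            resize_for_diameter(self._img(labels), 1.0, 100.0)

    def test_down_up_preserves_roi_count(self):
        for seed in range(5):
            scene = generate_scene(
                SceneConfig(canvas=(64, 64), n_cells=6, diameter_mean=12,
                            seed=seed)
            )
            down = resize_for_diameter(scene, 12.0, 6.0)
            back = resize_labels_back(down.labels, scene.spatial_shape)
            assert len(np.unique(back)) == len(np.unique(scene.labels))
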