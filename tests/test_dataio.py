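"""Label-map I/O and the dataset-preparation operators."""

import numpy as np
import pytest
import tifffile

from cellseg.dataio import (
    FormatError,
    LabeledImage,
    RangeError,
    RoiOverlapPolicy,
    enhance_contrast,
    filter_min_rois,
    mirror_image,
    read_label_map,
    read_manifest,
    remove_overlaps,
    split_quarters,
    write_label_map,
    write_manifest,
)


def _li(labels, pixels=None):
    labels = np.asarray(labels)
    if pixels is None:
        pixels = np.zeros(labels.shape, dtype=np.float32)
    return LabeledImage(pixels=pixels, labels=labels)


class TestLabelMapIO:
    @pytest.mark.parametrize("suffix", [".png", ".tif"])
    def test_round_trip_bit_exact(self, tmp_path, suffix, rng):
        labels = rng.integers(0, 5, size=(32, 40)).astype(np.int32)
        labels[0, 0] = 65535  # extreme representable id
        path = tmp_path / f"lab{suffix}"
        write_label_map(labels, path)
        assert np.array_equal(read_label_map(path), labels)

    def test_all_zero_map_round_trips(self, tmp_path):
        path = tmp_path / "zeros.tif"
        write_label_map(np.zeros((8, 8), np.int32), path)
        assert read_label_map(path).sum() == 0

    def test_float_file_rejected(self, tmp_path):
        path = tmp_path / "float.tif"
        tifffile.imwrite(path, np.zeros((4, 4), np.float32))
        with pytest.raises(FormatError):
            read_label_map(path)

    def test_missing_file_is_io_error(self, tmp_path):
        with pytest.raises(IOError):
            read_label_map(tmp_path / "nope.tif")

    def test_id_overflow_rejected(self, tmp_path):
        with pytest.raises(RangeError):
            write_label_map(np.full((4, 4), 70000, np.int64), tmp_path / "x.tif")

    def test_manifest_round_trip(self, tmp_path):
        from cellseg.dataio import write_image

        labels = np.zeros((8, 8), np.int32)
        labels[2:4, 2:4] = 1
        write_image(np.ones((8, 8), np.float32), tmp_path / "img.tif")
        write_label_map(labels, tmp_path / "lab.tif")
        write_manifest(
            [("img.tif", "lab.tif", ("cytoplasm",))], tmp_path / "manifest.json"
        )
        (loaded,) = read_manifest(tmp_path / "manifest.json")
        assert loaded.n_rois == 1
        assert loaded.channel_roles == ("cytoplasm",)


class TestRemoveOverlaps:
    def test_disjoint_rois_unchanged(self):
        a = np.array([[0, 0], [0, 1]])
        b = np.array([[5, 5], [5, 6]])
        out = remove_overlaps([a, b], shape=(8, 8))
        assert np.sum(out == 1) == 2 and np.sum(out == 2) == 2

    def test_mostly_overlapping_roi_removed(self):
        # ROI b (10 px) shares 8 px with ROI a (40 px): 8/10 = 0.8 > 0.75
        a = np.array([(0, c) for c in range(40)])
        b = np.array([(0, c) for c in range(32, 40)] + [(1, 0), (1, 1)])
        out = remove_overlaps([a, b], shape=(4, 48))
        assert np.sum(out == 1) == 40
        assert np.sum(out == 2) == 0

    def test_contested_pixels_to_nearest_centroid(self):
        # two 50-px ROI sharing 10 px (fraction 0.2 each): both kept
        a = np.array([(r, c) for r in range(5) for c in range(10)])
        b = np.array([(r, c) for r in range(5) for c in range(8, 18)])
        out = remove_overlaps([a, b], shape=(6, 20))
        assert np.sum(out > 0) == 90
        # centroids at cols 4.5 and 12.5: shared col 8 is nearer a (3.5 vs
        # 4.5) and shared col 9 nearer b (4.5 vs 3.5)
        assert np.all(out[:5, 8] == 1) and np.all(out[:5, 9] == 2)
        assert np.sum(out == 1) == 45 and np.sum(out == 2) == 45

    def test_empty_list_gives_empty_map(self):
        assert remove_overlaps([], shape=(4, 4)).sum() == 0

    def test_never_leaves_overlaps_and_matches_bruteforce(self, rng):
        """Randomised instances vs a per-pixel brute-force oracle."""
        for _ in range(25):
            n = int(rng.integers(2, 12))
            sets = []
            for _i in range(n):
                cy, cx = rng.integers(3, 29, 2)
                h, w = rng.integers(2, 7, 2)
                pix = [
                    (r, c)
                    for r in range(cy - h, cy + h)
                    for c in range(cx - w, cx + w)
                ]
                sets.append(np.array(pix))
            policy = RoiOverlapPolicy()
            out = remove_overlaps(sets, policy, shape=(40, 40))
            # brute-force removal decision
            canvas = np.zeros((40, 40), int)
            for s in sets:
                canvas[s[:, 0], s[:, 1]] += 1
            for i, s in enumerate(sets):
                frac = np.mean(canvas[s[:, 0], s[:, 1]] > 1)
                present = np.any(out == i + 1)
                assert present == (frac <= policy.removal_fraction)
                if present:
                    # non-contested pixels never reassigned
                    solo = s[canvas[s[:, 0], s[:, 1]] == 1]
                    assert np.all(out[solo[:, 0], solo[:, 1]] == i + 1)


class TestSplitQuarters:
    def test_512_gives_four_256_tiles(self):
        img = _li(np.zeros((512, 512), np.int32))
        tiles = split_quarters(img)
        assert len(tiles) == 4
        assert all(t.spatial_shape == (256, 256) for t in tiles)

    def test_odd_dims_remainder_to_last(self):
        tiles = split_quarters(_li(np.zeros((101, 100), np.int32)))
        assert tiles[0].spatial_shape == (50, 50)
        assert tiles[3].spatial_shape == (51, 50)

    def test_labeled_pixels_conserved_and_reindexed(self, rng):
        labels = np.zeros((60, 60), np.int32)
        labels[25:35, 25:35] = 7  # ROI spanning the centre cut
        labels[2:6, 2:6] = 3
        tiles = split_quarters(_li(labels))
        assert sum(int((t.labels > 0).sum()) for t in tiles) == int(
            (labels > 0).sum()
        )
        for t in tiles:
            ids = np.unique(t.labels)
            ids = ids[ids > 0]
            assert np.array_equal(ids, np.arange(1, ids.size + 1))


class TestEnhanceContrast:
    def test_constant_image_maps_to_zero(self):
        out = enhance_contrast(np.full((40, 40), 3.7))
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_all_zero_image_returns_zeros(self):
        assert np.all(enhance_contrast(np.zeros((20, 20))) == 0)

    def test_bright_pixel_formula_matches_direct_evaluation(self):
        from scipy import ndimage

        img = np.zeros((64, 64))
        img[32, 32] = 10.0
        out = enhance_contrast(img, kernel_width=5.0)
        smooth = ndimage.gaussian_filter(img, sigma=5.0)
        denom = np.maximum(smooth, 1e-6 * 10.0)
        expected = (img - smooth) / denom
        assert np.allclose(out, expected)
        assert out[32, 32] > 0  # positive peak at the bright pixel

    def test_commutes_with_mirroring(self, rng):
        img = rng.random((48, 48))
        a = enhance_contrast(img[::-1, ::-1], kernel_width=4.0)
        b = enhance_contrast(img, kernel_width=4.0)[::-1, ::-1]
        assert np.allclose(a, b, atol=1e-10)


class TestMirrorAndFilter:
    def test_mirror_is_involution(self, rng):
        img = _li(rng.integers(0, 4, (10, 12)).astype(np.int32), rng.random((10, 12)))
        twice = mirror_image(mirror_image(img))
        assert np.array_equal(twice.labels, img.labels)
        assert np.allclose(twice.pixels, img.pixels)

    def test_mirror_flips_both_axes(self):
        img = _li(np.array([[1, 0], [0, 2]], np.int32))
        assert np.array_equal(mirror_image(img).labels, [[2, 0], [0, 1]])

    @pytest.mark.parametrize("n,kept", [(4, False), (5, True), (6, True)])
    def test_min_roi_boundary(self, n, kept):
        labels = np.zeros((20, 20), np.int32)
        for i in range(n):
            labels[2 * i, :2] = i + 1
        out = filter_min_rois([_li(labels)], min_rois=5)
        assert (len(out) == 1) == kept

    def test_empty_input(self):
        assert filter_min_rois([]) == []
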