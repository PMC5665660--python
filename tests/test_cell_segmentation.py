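import numpy as np
import pytest

from lipidquant.cell_segmentation import (
    CellLabelMask,
    SegmentationParams,
    build_seed_mask,
    dilate_labels,
    remove_border_cells,
    segment_cells,
)
from lipidquant.geometry import rasterize_disk
from lipidquant.image_io import SeedSet


def _disk_image(center, radius, shape=(96, 96), fg=200, bg=10):
    img = np.full(shape, bg, dtype=np.uint8)
    px = rasterize_disk(center, radius, shape)
    img[px[:, 0], px[:, 1]] = fg
    return img, px


def _mask_from(labels, seed_of=None):
    labels = np.asarray(labels, dtype=np.int32)
    if seed_of is None:
        seed_of = {}
        for lid in np.unique(labels):
            if lid > 0:
                r, c = np.argwhere(labels == lid)[0]
                seed_of[int(lid)] = (int(r), int(c))
    return CellLabelMask(labels=labels, seed_of=seed_of)


class TestBuildSeedMask:
    def test_radius_one_center_stamp(self):
        seeds = SeedSet(points=[(32, 32)], image_shape=(64, 64))
        mask = build_seed_mask(seeds, 1)
        assert mask.sum() == 9
        assert mask[31:34, 31:34].all()

    def test_corner_stamp_clipped(self):
        seeds = SeedSet(points=[(0, 0)], image_shape=(64, 64))
        full = build_seed_mask(SeedSet(points=[(32, 32)], image_shape=(64, 64)), 3).sum()
        clipped = build_seed_mask(seeds, 3).sum()
        assert 0 < clipped < full

    def test_adjacent_seeds_union_to_one_region(self):
        from skimage.measure import label

        seeds = SeedSet(points=[(32, 32), (32, 33)], image_shape=(64, 64))
        mask = build_seed_mask(seeds, 2)
        assert label(mask).max() == 1

    def test_nonpositive_radius_rejected(self):
        seeds = SeedSet(points=[(5, 5)], image_shape=(16, 16))
        with pytest.raises(ValueError):
            build_seed_mask(seeds, 0)


class TestSegmentCells:
    def test_recovers_bright_disk_with_high_dice(self):
        img, truth_px = _disk_image((48, 48), 20)
        seeds = SeedSet(points=[(48, 48)], image_shape=img.shape)
        mask = segment_cells(img, seeds, SegmentationParams())
        got = mask.labels == 1
        truth = np.zeros_like(got)
        truth[truth_px[:, 0], truth_px[:, 1]] = True
        dice = 2 * (got & truth).sum() / (got.sum() + truth.sum())
        assert dice >= 0.95

    def test_two_separated_blobs_two_labels_containing_their_seeds(self):
        img = np.full((96, 96), 10, dtype=np.uint8)
        for ctr in [(30, 30), (70, 70)]:
            px = rasterize_disk(ctr, 14, img.shape)
            img[px[:, 0], px[:, 1]] = 200
        seeds = SeedSet(points=[(30, 30), (70, 70)], image_shape=img.shape)
        mask = segment_cells(img, seeds, SegmentationParams())
        assert mask.n_cells == 2
        for lid, seed in mask.seed_of.items():
            assert mask.labels[seed] == lid

    def test_seed_in_uniform_background_is_flagged(self):
        img = np.full((96, 96), 10, dtype=np.uint8)
        px = rasterize_disk((30, 30), 14, img.shape)
        img[px[:, 0], px[:, 1]] = 200
        seeds = SeedSet(points=[(30, 30), (75, 75)], image_shape=img.shape)
        with pytest.warns(UserWarning, match="no usable cell region"):
            mask = segment_cells(img, seeds, SegmentationParams())
        assert mask.n_cells == 1
        assert (75, 75) in mask.failed_seeds

    def test_no_seeds_rejected(self):
        img = np.zeros((32, 32), dtype=np.uint8)
        with pytest.raises(ValueError, match="seed"):
            segment_cells(img, SeedSet(points=[], image_shape=(32, 32)))

    def test_deterministic(self):
        img, _ = _disk_image((48, 48), 20)
        seeds = SeedSet(points=[(48, 48)], image_shape=img.shape)
        a = segment_cells(img, seeds).labels
        b = segment_cells(img, seeds).labels
        assert (a == b).all()


class TestRemoveBorderCells:
    def test_interior_retained_border_removed(self):
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[0, 5] = 1  # touches row 0
        labels[7:9, 7:9] = 2  # interior
        out = remove_border_cells(_mask_from(labels, {1: (0, 5), 2: (7, 7)}))
        assert out.n_cells == 1
        assert set(np.unique(out.labels)) == {0, 1}
        assert (out.labels[7:9, 7:9] == 1).all()

    def test_matches_border_scan_oracle_on_random_masks(self, rng):
        for _ in range(20):
            labels = rng.integers(0, 5, (32, 32), dtype=np.int32)
            seed_of = {}
            for lid in np.unique(labels):
                if lid > 0:
                    r, c = np.argwhere(labels == lid)[0]
                    seed_of[int(lid)] = (int(r), int(c))
            out = remove_border_cells(_mask_from(labels, seed_of))
            # oracle: scan border pixels, collect doomed labels
            doomed = set()
            for r in range(32):
                for c in range(32):
                    if r in (0, 31) or c in (0, 31):
                        if labels[r, c] > 0:
                            doomed.add(labels[r, c])
            survivors = sorted(set(np.unique(labels)) - {0} - doomed)
            assert out.n_cells == len(survivors)
            for new, old in enumerate(survivors, start=1):
                assert ((out.labels == new) == (labels == old)).all()

    def test_border_predicate_false_after_removal(self):
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[0:4, 0:4] = 1
        labels[8:11, 8:11] = 2
        out = remove_border_cells(_mask_from(labels))
        border = np.concatenate(
            [out.labels[0, :], out.labels[-1, :], out.labels[:, 0], out.labels[:, -1]]
        )
        assert (border == 0).all()


class TestDilateLabels:
    def test_radius_zero_identity(self):
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[5:8, 5:8] = 1
        out = dilate_labels(_mask_from(labels), 0)
        assert (out.labels == labels).all()

    def test_single_pixel_grows_to_disk(self):
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[8, 8] = 1
        out = dilate_labels(_mask_from(labels), 1)
        expected = {(8, 8), (7, 8), (9, 8), (8, 7), (8, 9)}
        assert {tuple(p) for p in np.argwhere(out.labels == 1)} == expected

    def test_contested_pixels_matched_to_brute_force_oracle(self):
        labels = np.zeros((16, 24), dtype=np.int32)
        labels[8, 5] = 1
        labels[8, 9] = 2  # 3 px apart (gap of 3 columns)
        out = dilate_labels(_mask_from(labels, {1: (8, 5), 2: (8, 9)}), 2)
        # brute force: per pixel, distance to each label's original pixel
        for r in range(16):
            for c in range(24):
                d1 = np.hypot(r - 8, c - 5)
                d2 = np.hypot(r - 8, c - 9)
                if min(d1, d2) > 2:
                    assert out.labels[r, c] == 0
                elif d1 < d2:
                    assert out.labels[r, c] == 1
                elif d2 < d1:
                    assert out.labels[r, c] == 2
                else:  # tie -> lower label id
                    assert out.labels[r, c] == 1

    def test_extensive_no_label_loses_pixels(self, rng):
        labels = np.zeros((24, 24), dtype=np.int32)
        labels[4:8, 4:8] = 1
        labels[10:13, 10:13] = 2
        out = dilate_labels(_mask_from(labels), 3)
        for lid in (1, 2):
            assert ((labels == lid) <= (out.labels == lid)).all()

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            dilate_labels(_mask_from(np.zeros((4, 4), dtype=np.int32)), -1)
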