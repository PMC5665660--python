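import math

import numpy as np
import pytest

from lipidquant.cell_segmentation import CellLabelMask
from lipidquant.droplet_segmentation import (
    DropletComponent,
    HSVParams,
    assign_multiplicity,
    background_correct,
    crack_perimeter,
    estimate_reference_area,
    hsv_segment,
    label_droplets,
)
from lipidquant.geometry import rasterize_disk
from lipidquant.image_io import FieldOfView


def _color_fov(rgb_triplets):
    """1 x n image holding the given RGB colors."""
    px = np.array([rgb_triplets], dtype=np.uint8)
    return FieldOfView(pixels=px)


def hexcone_hsv(r, g, b):
    """Independent oracle: textbook hexcone RGB -> HSV on [0,1] channels."""
    r, g, b = r / 255.0, g / 255.0, b / 255.0
    mx, mn = max(r, g, b), min(r, g, b)
    delta = mx - mn
    if delta == 0:
        h = 0.0
    elif mx == r:
        h = (60 * ((g - b) / delta)) % 360
    elif mx == g:
        h = 60 * ((b - r) / delta) + 120
    else:
        h = 60 * ((r - g) / delta) + 240
    s = 0.0 if mx == 0 else delta / mx
    return h, s, mx


def _cells(labels):
    labels = np.asarray(labels, dtype=np.int32)
    seed_of = {
        int(l): tuple(np.argwhere(labels == l)[0]) for l in np.unique(labels) if l > 0
    }
    return CellLabelMask(labels=labels, seed_of=seed_of)


class TestHSVSegment:
    def test_pure_green_inside_default_gate(self):
        fov = _color_fov([(0, 255, 0)])
        assert hsv_segment(fov, HSVParams(hue_range_deg=(90, 150), sat_min=0.5, val_min=0.2))[0, 0]

    def test_pure_red_outside_green_gate(self):
        fov = _color_fov([(255, 0, 0)])
        assert not hsv_segment(fov, HSVParams(hue_range_deg=(90, 150), sat_min=0.5, val_min=0.2))[0, 0]

    def test_black_fails_value_gate_regardless_of_hue(self):
        fov = _color_fov([(0, 0, 0)])
        assert not hsv_segment(fov, HSVParams(val_min=0.2))[0, 0]

    def test_wraparound_hue_window_selects_reds(self):
        params = HSVParams(hue_range_deg=(330, 30), sat_min=0.5, val_min=0.2)
        assert hsv_segment(_color_fov([(255, 0, 0)]), params)[0, 0]
        assert not hsv_segment(_color_fov([(0, 255, 0)]), params)[0, 0]

    def test_matches_hexcone_oracle_on_corners_and_random_colors(self, rng):
        corners = [
            (0, 0, 0), (255, 0, 0), (0, 255, 0), (0, 0, 255),
            (255, 255, 0), (255, 0, 255), (0, 255, 255), (255, 255, 255),
        ]
        colors = corners + [tuple(c) for c in rng.integers(0, 256, (100, 3))]
        params = HSVParams(hue_range_deg=(60, 180), sat_min=0.25, val_min=0.15)
        got = hsv_segment(_color_fov(colors), params)[0]
        for i, (r, g, b) in enumerate(colors):
            h, s, v = hexcone_hsv(r, g, b)
            expected = (60 <= h <= 180) and s >= 0.25 and v >= 0.15
            assert got[i] == expected, (r, g, b, h, s, v)

    def test_empty_hue_range_rejected(self):
        with pytest.raises(ValueError):
            HSVParams(hue_range_deg=(120, 120))


class TestBackgroundCorrect:
    def test_droplet_inside_cell_unchanged(self):
        cells = _cells(np.ones((8, 8)))
        ld = np.zeros((8, 8), dtype=bool)
        ld[3:5, 3:5] = True
        assert (background_correct(ld, cells) == ld).all()

    def test_droplet_outside_cells_removed(self):
        cells = _cells(np.zeros((8, 8)))
        ld = np.zeros((8, 8), dtype=bool)
        ld[3:5, 3:5] = True
        assert not background_correct(ld, cells).any()

    def test_straddling_droplet_matches_setwise_and_oracle(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[:, :5] = 1
        cells = _cells(labels)
        ld = np.zeros((10, 10), dtype=bool)
        ld[4:7, 3:8] = True
        out = background_correct(ld, cells)
        for r in range(10):
            for c in range(10):
                assert out[r, c] == (ld[r, c] and labels[r, c] > 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            background_correct(np.zeros((4, 4), dtype=bool), _cells(np.zeros((5, 5))))


def flood_fill_count(mask):
    """Recursive-style (explicit stack) 8-connected component counter."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    n = 0
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if mask[r0, c0] and not seen[r0, c0]:
                n += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < mask.shape[0]
                                and 0 <= cc < mask.shape[1]
                                and mask[rr, cc]
                                and not seen[rr, cc]
                            ):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
    return n


class TestLabelDroplets:
    def test_diagonal_pixels_are_one_component(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[2, 2] = mask[3, 3] = True
        comps = label_droplets(mask, min_area_px=1)
        assert len(comps) == 1
        assert comps[0].area_px == 2

    def test_empty_mask_yields_empty_list(self):
        assert label_droplets(np.zeros((6, 6), dtype=bool), 1) == []

    def test_component_count_matches_flood_fill_oracle(self, rng):
        for _ in range(50):
            mask = rng.random((20, 20)) < 0.35
            comps = label_droplets(mask, min_area_px=1)
            assert len(comps) == flood_fill_count(mask)

    def test_areas_conserve_foreground_count(self, rng):
        mask = rng.random((30, 30)) < 0.3
        comps = label_droplets(mask, min_area_px=1)
        assert sum(c.area_px for c in comps) == int(mask.sum())

    def test_min_area_filter(self, rng):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1, 1] = True  # area 1
        mask[5:8, 5:8] = True  # area 9
        comps = label_droplets(mask, min_area_px=4)
        assert len(comps) == 1
        assert comps[0].area_px == 9

    @pytest.mark.parametrize("radius", [4, 5, 6, 8, 10])
    def test_disk_circularity_in_sanity_band(self, radius):
        shape = (2 * radius + 5, 2 * radius + 5)
        mask = np.zeros(shape, dtype=bool)
        px = rasterize_disk((radius + 2, radius + 2), radius, shape)
        mask[px[:, 0], px[:, 1]] = True
        comp = label_droplets(mask, 1)[0]
        assert 0.85 <= comp.circularity <= 1.1

    def test_perimeter_positive_even_for_single_pixel(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        assert crack_perimeter(mask) > 0


class TestReferenceArea:
    def _comp(self, area, circ):
        return DropletComponent(
            pixels=np.zeros((area, 2), dtype=int), area_px=area, perimeter_px=1.0,
            centroid=(0.0, 0.0), circularity=circ, eccentricity=0.0,
        )

    def test_median_of_circular_components(self):
        comps = [self._comp(a, 0.95) for a in (10, 12, 14, 16, 18)]
        ref = estimate_reference_area(comps, 0.8)
        assert ref.ref_area_px == 14
        assert ref.n_support == 5

    def test_single_component(self):
        ref = estimate_reference_area([self._comp(42, 0.9)], 0.8)
        assert ref.ref_area_px == 42
        assert ref.n_support == 1

    def test_fallback_when_nothing_circular(self):
        comps = [self._comp(a, 0.4) for a in (10, 20, 30)]
        with pytest.warns(UserWarning, match="fallback|falls back"):
            ref = estimate_reference_area(comps, 0.8)
        assert ref.fallback
        assert ref.ref_area_px == 20

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            estimate_reference_area([], 0.8)


class TestAssignMultiplicity:
    def _comp(self, area, circ):
        return DropletComponent(
            pixels=np.zeros((1, 2), dtype=int), area_px=area, perimeter_px=1.0,
            centroid=(0.0, 0.0), circularity=circ, eccentricity=0.0,
        )

    @pytest.mark.parametrize(
        "area_factor,circ,expected",
        [
            (1.0, 0.95, 1),  # reference-sized and round
            (2.0, 0.5, 2),  # double area, elongated
            (4.0, 0.4, 3),  # far past double: capped at 3
            (2.0, 0.9, 1),  # round overrides area
            (1.4, 0.3, 1),  # below the pair threshold
            (2.5, 0.5, 2),  # boundary: k3 inclusive
        ],
    )
    def test_rule_table(self, area_factor, circ, expected):
        from lipidquant.droplet_segmentation import ReferenceArea

        ref = ReferenceArea(ref_area_px=40.0, n_support=5)
        comp = assign_multiplicity(self._comp(int(40 * area_factor), circ), ref)
        assert comp.multiplicity == expected
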