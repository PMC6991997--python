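"""Adaptive thresholding, morphological cleaning, seeded region growing,
region properties and optic-disc candidate selection."""

import numpy as np
import pytest

from odseg._util import circle_mask, ellipse_interior
from odseg.errors import InputError, SegmentationError
from odseg.segment import (
    RegionProps,
    SelectionConfig,
    adaptive_threshold,
    compute_region_props,
    eccentricity_from_axes,
    morph_clean,
    region_grow,
    select_od_region,
)


def oracle_region_grow(v, seed, tolerance, mask=None):
    """Independent plain-Python best-first growth with the same rules:
    8-connected frontier, running mean, lowest-(row, col) tie break."""
    h, w = v.shape
    allowed = (
        {(r, c) for r in range(h) for c in range(w)}
        if mask is None
        else {tuple(p) for p in np.argwhere(mask)}
    )
    region = {tuple(map(int, seed))}
    total = float(v[seed])
    frontier = set()

    def neighbors(p):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr or dc:
                    q = (p[0] + dr, p[1] + dc)
                    if 0 <= q[0] < h and 0 <= q[1] < w:
                        yield q

    for q in neighbors(tuple(map(int, seed))):
        if q in allowed:
            frontier.add(q)
    while frontier:
        mean = total / len(region)
        best = min(frontier, key=lambda p: (abs(float(v[p]) - mean), p))
        if abs(float(v[best]) - mean) > tolerance:
            break
        frontier.discard(best)
        region.add(best)
        total += float(v[best])
        for q in neighbors(best):
            if q in allowed and q not in region:
                frontier.add(q)
    out = np.zeros((h, w), dtype=bool)
    for r, c in region:
        out[r, c] = True
    return out


class TestAdaptiveThreshold:
    def test_constant_raster_empty_mask(self):
        roi = np.ones((30, 30), dtype=bool)
        assert not adaptive_threshold(np.full((30, 30), 0.4), roi).any()

    def test_bright_disc_interior_captured(self):
        img = np.full((100, 100), 0.2)
        disc = circle_mask((100, 100), (50, 50), 20)
        img[disc] = 0.8
        roi = np.ones((100, 100), dtype=bool)
        mask = adaptive_threshold(img, roi, sigma=7.0)
        interior = circle_mask((100, 100), (50, 50), 12)
        assert (mask & interior).sum() == interior.sum()

    def test_single_bright_pixel_detected(self):
        img = np.full((41, 41), 0.3)
        img[20, 20] = 0.9
        roi = np.ones((41, 41), dtype=bool)
        assert adaptive_threshold(img, roi, sigma=7.0)[20, 20]

    def test_offset_invariance(self, rng):
        img = rng.uniform(0, 1, (40, 40))
        roi = np.ones((40, 40), dtype=bool)
        m1 = adaptive_threshold(img, roi)
        m2 = adaptive_threshold(img + 0.2, roi)
        assert np.array_equal(m1, m2)


class TestMorphClean:
    def test_empty_stays_empty(self):
        assert not morph_clean(np.zeros((30, 30), dtype=bool)).any()

    def test_full_mask_keeps_bulk(self):
        out = morph_clean(np.ones((60, 60), dtype=bool))
        assert out[10:50, 10:50].all()

    def test_small_square_removed(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[18:23, 18:23] = True  # 5x5 < disc diameter 13
        assert not morph_clean(mask).any()


class TestRegionGrow:
    def test_constant_raster_fills_everything(self):
        v = np.full((12, 12), 0.5)
        assert region_grow(v, (6, 6), 0.05).all()

    def test_two_level_raster_stays_in_bright_region(self):
        v = np.full((20, 20), 0.3)
        v[:, 10:] = 0.8
        out = region_grow(v, (10, 15), 0.05)
        assert out[:, 10:].all() and not out[:, :10].any()

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_independent_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        v = np.round(rng.uniform(0, 1, (32, 32)), 2)
        seed = (int(rng.integers(4, 28)), int(rng.integers(4, 28)))
        got = region_grow(v, seed, 0.05)
        oracle = oracle_region_grow(v, seed, 0.05)
        assert np.array_equal(got, oracle)

    def test_respects_mask(self):
        v = np.full((20, 20), 0.5)
        roi = circle_mask((20, 20), (10, 10), 6)
        out = region_grow(v, (10, 10), 0.05, mask=roi)
        assert np.array_equal(out, roi)

    def test_single_component_containing_seed(self, rng):
        from scipy import ndimage as ndi

        v = rng.uniform(0, 1, (30, 30))
        out = region_grow(v, (15, 15), 0.1)
        labels, n = ndi.label(out, structure=np.ones((3, 3)))
        assert n == 1 and out[15, 15]

    def test_seed_outside_raises(self):
        with pytest.raises(InputError):
            region_grow(np.zeros((5, 5)), (9, 9), 0.05)
        with pytest.raises(InputError):
            region_grow(np.zeros((5, 5)), (2, 2), 0.05, mask=np.zeros((5, 5), dtype=bool))


class TestRegionProps:
    def test_eccentricity_formula(self):
        assert eccentricity_from_axes(5.0, 3.0) == pytest.approx(0.8, abs=1e-12)
        assert eccentricity_from_axes(4.0, 4.0) == 0.0
        assert eccentricity_from_axes(0.0, 0.0) == 0.0

    def test_filled_circle_near_zero_eccentricity(self):
        mask = circle_mask((60, 60), (30, 30), 20)
        (p,) = compute_region_props(mask)
        assert p.eccentricity <= 0.1
        assert p.area == mask.sum()

    def test_thin_bar_near_unit_eccentricity(self):
        mask = np.zeros((10, 40), dtype=bool)
        mask[5, 5:35] = True
        (p,) = compute_region_props(mask)
        assert p.eccentricity >= 0.99

    @pytest.mark.parametrize("q", [0.5, 0.7, 0.9])
    def test_rasterized_ellipse_eccentricity(self, q):
        a = 30.0
        mask = ellipse_interior((100, 100), (50, 50), (a, q * a), 0.3)
        (p,) = compute_region_props(mask)
        assert abs(p.eccentricity - np.sqrt(1 - q**2)) <= 0.05

    def test_empty_mask_empty_list(self):
        assert compute_region_props(np.zeros((5, 5), dtype=bool)) == []


def _props(area, ecc):
    return RegionProps(
        label=1,
        area=area,
        centroid=(0.0, 0.0),
        major_axis=10.0,
        minor_axis=10.0 * np.sqrt(1 - ecc**2),
        eccentricity=ecc,
        mask=np.zeros((2, 2), dtype=bool),
    )


class TestSelection:
    CFG = SelectionConfig(avg_area=1000.0)

    def test_single_in_range_candidate_returned(self):
        chosen, low = select_od_region([_props(1000, 0.5)], [], self.CFG)
        assert chosen.area == 1000 and not low

    def test_smallest_eccentricity_wins(self):
        chosen, _ = select_od_region(
            [_props(1000, 0.1)], [_props(1000, 0.9)], self.CFG
        )
        assert chosen.eccentricity == 0.1

    def test_area_range_filters_before_eccentricity(self):
        chosen, low = select_od_region(
            [_props(2000, 0.2), _props(1000, 0.5)], [], self.CFG
        )
        assert chosen.area == 1000 and chosen.eccentricity == 0.5 and not low

    def test_fallback_flags_low_confidence(self):
        chosen, low = select_od_region([_props(2000, 0.2)], [], self.CFG)
        assert chosen.area == 2000 and low

    def test_no_candidates_raises(self):
        with pytest.raises(SegmentationError):
            select_od_region([], [], self.CFG)
        with pytest.raises(SegmentationError):
            select_od_region([_props(5000, 0.99)], [], self.CFG)
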