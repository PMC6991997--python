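"""Haze-line de-hazing: airlight, line assignment, transmission, inversion."""

import numpy as np
import pytest

from odseg.dehaze import (
    HazeEstimate,
    assign_haze_lines,
    dehaze,
    dehaze_image,
    estimate_airlight,
    estimate_transmission,
    fibonacci_sphere,
    smooth_transmission,
)
from odseg.errors import InputError, ParameterError
from odseg.synth import SceneSpec, apply_haze, generate_fundus


def hazy_fixture(seed=11, t_range=(0.1, 0.7), airlight=(0.9, 0.9, 0.8)):
    """Haze-free scene, smooth transmission field, hazy version; no noise so
    the forward model is exact.

    The default range includes near-opaque pockets (t ~ 0.1): only where
    transmission is low do observed colors approach the airlight, which is
    what makes brightest-pixel airlight estimation well-posed.
    """
    spec = SceneSpec(seed=seed, noise_sigma=0.0, lesion_count=0)
    clean, gt = generate_fundus(spec)
    from scipy import ndimage as ndi

    rng = np.random.default_rng(seed + 1)
    f = ndi.gaussian_filter(rng.standard_normal(clean.shape[:2]), 60)
    f = (f - f.min()) / (f.max() - f.min())
    t = t_range[0] + (t_range[1] - t_range[0]) * f
    hazy = apply_haze(clean, airlight, t)
    fov = clean.sum(axis=2) > 0
    hazy[~fov] = 0.0
    return clean, hazy, t, np.asarray(airlight), fov


class TestAirlight:
    def test_constant_image(self):
        img = np.full((10, 10, 3), 0.42)
        fov = np.ones((10, 10), dtype=bool)
        assert np.allclose(estimate_airlight(img, fov), 0.42)

    def test_saturated_patch_wins(self, rng):
        img = rng.uniform(0.1, 0.5, (50, 50, 3))
        img[10:15, 10:15] = 1.0
        fov = np.ones((50, 50), dtype=bool)
        assert np.allclose(estimate_airlight(img, fov), 1.0)

    def test_empty_fov_raises(self):
        with pytest.raises(InputError):
            estimate_airlight(np.zeros((4, 4, 3)), np.zeros((4, 4), dtype=bool))

    def test_recovers_airlight_on_hazy_scene(self):
        _, hazy, _, airlight, fov = hazy_fixture()
        est = estimate_airlight(hazy, fov)
        assert np.all(np.abs(est - airlight) <= 0.1)


class TestHazeLines:
    def test_fibonacci_sphere_unit_norm(self):
        d = fibonacci_sphere(500)
        assert d.shape == (500, 3)
        assert np.allclose(np.linalg.norm(d, axis=1), 1.0)

    def test_opposite_colors_get_different_labels(self):
        a = np.array([0.5, 0.5, 0.5])
        img = np.array([[[0.9, 0.5, 0.5], [0.1, 0.5, 0.5]]])
        labels = assign_haze_lines(img, a, 100)
        assert labels[0, 0] != labels[0, 1]

    def test_matches_exhaustive_nearest_direction(self, rng):
        """Every assigned direction is the brute-force angular nearest."""
        a = np.array([0.4, 0.4, 0.4])
        img = rng.uniform(0, 1, (10, 10, 3))
        n = 1000
        labels = assign_haze_lines(img, a, n)
        dirs = fibonacci_sphere(n)
        for i in range(10):
            for j in range(10):
                diff = img[i, j] - a
                r = np.linalg.norm(diff)
                if r == 0:
                    continue
                unit = diff / r
                best = int(np.argmax([unit @ d for d in dirs]))
                assert labels[i, j] == best

    def test_requires_two_directions(self):
        with pytest.raises(ParameterError):
            assign_haze_lines(np.zeros((2, 2, 3)), np.zeros(3), 1)


class TestTransmission:
    def test_max_radius_pixel_gets_unit_transmission(self):
        a = np.zeros(3)
        img = np.array([[[0.2, 0.0, 0.0], [0.8, 0.0, 0.0]]])
        labels = assign_haze_lines(img, a, 100)
        t = estimate_transmission(img, a, labels)
        assert t[0, 1] == 1.0
        assert np.isclose(t[0, 0], 0.25)

    def test_zero_radius_clamped_to_floor(self):
        a = np.full(3, 0.5)
        img = np.full((3, 3, 3), 0.5)
        img[0, 0] = (0.9, 0.5, 0.5)
        labels = assign_haze_lines(img, a, 100)
        t = estimate_transmission(img, a, labels, t_floor=0.1)
        assert t[1, 1] == 0.1

    def test_known_spatially_varying_transmission_recovered(self, rng):
        """Five flat colors hazed with known t in [0.4, 1], one t=1 pixel per
        color: the per-line max radius then equals the haze-free radius."""
        colors = np.array(
            [[0.6, 0.2, 0.1], [0.2, 0.6, 0.1], [0.1, 0.2, 0.6], [0.5, 0.5, 0.1], [0.2, 0.2, 0.2]]
        )
        h, w = 50, 50
        idx = rng.integers(0, 5, (h, w))
        clean = colors[idx]
        t = rng.uniform(0.4, 1.0, (h, w))
        for c in range(5):  # guarantee a haze-free pixel on every line
            where = np.argwhere(idx == c)
            r, cc = where[0]
            t[r, cc] = 1.0
        a = (0.95, 0.95, 0.9)
        hazy = apply_haze(clean, a, t)
        labels = assign_haze_lines(hazy, np.asarray(a), 500)
        t_hat = estimate_transmission(hazy, np.asarray(a), labels)
        frac = np.mean(np.abs(t_hat - t) <= 0.15)
        assert frac >= 0.90


class TestSmoothing:
    def test_lambda_zero_is_identity(self, rng):
        t = rng.uniform(0.2, 1.0, (20, 20))
        out = smooth_transmission(t, np.zeros((20, 20, 3)), lam=0.0)
        assert np.array_equal(out, t)

    def test_constant_is_fixed_point(self):
        t = np.full((20, 20), 0.6)
        for lam in (0.05, 0.5):
            out = smooth_transmission(t, np.zeros((20, 20, 3)), lam=lam)
            assert np.allclose(out, 0.6, atol=1e-9)

    def test_checkerboard_range_shrinks(self):
        t = np.indices((20, 20)).sum(axis=0) % 2 * 0.8 + 0.2
        out = smooth_transmission(t, np.zeros((20, 20, 3)), lam=0.5)
        assert out.max() - out.min() < t.max() - t.min()


class TestDehaze:
    def test_unit_transmission_identity(self, rng):
        img = rng.uniform(0, 1, (8, 8, 3))
        est = HazeEstimate(np.array([0.9, 0.9, 0.8]), np.ones((8, 8)), 500)
        assert np.allclose(dehaze(img, est), img)

    def test_exact_inversion_with_true_parameters(self, rng):
        img = rng.uniform(0.05, 0.95, (16, 16, 3))
        a = (0.9, 0.9, 0.8)
        t = np.full((16, 16), 0.6)
        hazy = apply_haze(img, a, t)
        est = HazeEstimate(np.asarray(a), t, 500)
        assert np.max(np.abs(dehaze(hazy, est) - img)) <= 1e-6

    def test_full_chain_reduces_rmse_and_stays_in_range(self):
        clean, hazy, _, _, fov = hazy_fixture(seed=21)
        out, est = dehaze_image(hazy, fov)
        assert out.min() >= 0.0 and out.max() <= 1.0
        rmse_hazy = np.sqrt(np.mean((hazy[fov] - clean[fov]) ** 2))
        rmse_out = np.sqrt(np.mean((out[fov] - clean[fov]) ** 2))
        assert rmse_out < rmse_hazy

    def test_green_contrast_does_not_decrease(self):
        clean, hazy, _, _, fov = hazy_fixture(seed=31)
        out, _ = dehaze_image(hazy, fov)
        assert out[..., 1][fov].std() >= hazy[..., 1][fov].std()
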