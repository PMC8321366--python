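import numpy as np
import pytest
from scipy.spatial import Delaunay

from artpalette import gamut
from conftest import ellipse_points


def brute_force_ndc(lab, mode):
    cells = set()
    for p in np.asarray(lab).reshape(-1, 3):
        if mode == "lab-3d":
            cells.add((int(np.floor(p[0])), int(np.floor(p[1])), int(np.floor(p[2]))))
        else:
            cells.add((int(np.floor(p[1])), int(np.floor(p[2]))))
    return len(cells)


def delaunay_volume(points):
    """Tetrahedra-sum volume, an algorithmically independent hull oracle."""
    tri = Delaunay(points)
    vol = 0.0
    for simplex in tri.simplices:
        a, b, c, d = points[simplex]
        vol += abs(np.linalg.det(np.column_stack([b - a, c - a, d - a]))) / 6.0
    return vol


class TestDiscernibleColors:
    def test_uniform_image_is_one_cell(self):
        img = np.full((10, 10, 3), [50.0, 10.0, -20.0])
        assert gamut.count_discernible_colors(img, "lab-3d") == 1
        assert gamut.count_discernible_colors(img, "ab-2d") == 1

    def test_two_distant_colors(self):
        img = np.array([[[50.0, 0, 0], [50.0, 50, 0]]])
        assert gamut.count_discernible_colors(img) == 2

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("mode", ["lab-3d", "ab-2d"])
    def test_matches_brute_force_oracle(self, seed, mode):
        rng = np.random.default_rng(seed)
        img = rng.uniform([-10, -60, -60], [100, 60, 60], size=(64, 64, 3))
        assert gamut.count_discernible_colors(img, mode) == brute_force_ndc(img, mode)

    def test_permutation_and_duplication_invariance(self, rng):
        img = rng.uniform(0, 100, size=(16, 16, 3))
        n = gamut.count_discernible_colors(img)
        shuffled = rng.permutation(img.reshape(-1, 3)).reshape(img.shape)
        assert gamut.count_discernible_colors(shuffled) == n
        assert gamut.count_discernible_colors(np.tile(img, (2, 1, 1))) == n

    def test_2d_count_never_exceeds_3d(self, rng):
        img = rng.uniform(0, 100, size=(32, 32, 3))
        assert gamut.count_discernible_colors(img, "ab-2d") <= gamut.count_discernible_colors(img, "lab-3d")

    def test_monotone_under_added_pixels(self, rng):
        base = rng.uniform(0, 100, size=(50, 3))
        more = np.vstack([base, rng.uniform(0, 100, size=(20, 3))])
        assert gamut.count_discernible_colors(more) >= gamut.count_discernible_colors(base)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gamut.count_discernible_colors(np.empty((0, 3)))


class TestGamutVolume:
    def test_uniform_image_degenerate(self):
        img = np.full((5, 5, 3), [50.0, 0.0, 0.0])
        res = gamut.gamut_volume(img)
        assert res.volume == 0.0 and res.degenerate

    def test_coplanar_cloud_degenerate(self, rng):
        pts = np.column_stack([rng.uniform(0, 10, 50), rng.uniform(0, 10, 50), np.zeros(50)])
        assert gamut.gamut_volume(pts).degenerate

    def test_axis_aligned_cube(self):
        corners = np.array(
            [[L, a, b] for L in (40, 50) for a in (0, 10) for b in (0, 10)], dtype=float
        )
        res = gamut.gamut_volume(corners)
        assert res.volume == pytest.approx(1000.0)
        assert not res.degenerate

    def test_matches_delaunay_oracle(self, rng):
        pts = rng.normal(size=(500, 3)) * [20, 15, 10] + [50, 0, 0]
        res = gamut.gamut_volume(pts)
        assert res.volume == pytest.approx(delaunay_volume(pts), rel=1e-6)

    def test_monotone_under_added_points(self, rng):
        base = rng.normal(size=(100, 3)) * 10
        more = np.vstack([base, rng.normal(size=(50, 3)) * 10])
        assert gamut.gamut_volume(more).volume >= gamut.gamut_volume(base).volume

    def test_cell_count_mode(self):
        img = np.array([[[50.2, 0.5, 0.5], [50.7, 0.1, 0.9], [10.0, 20.0, 30.0]]])
        assert gamut.gamut_volume(img, mode="cells").volume == 2.0


class TestEllipseFit:
    def test_noise_free_recovery(self, rng):
        t = rng.uniform(0, 2 * np.pi, 200)
        pts = ellipse_points((5, -3), 20, 10, 30, t)
        e = gamut.fit_gamut_ellipse(pts)
        assert e.center == pytest.approx((5, -3), abs=1e-6)
        assert e.semi_major == pytest.approx(20, abs=1e-6)
        assert e.semi_minor == pytest.approx(10, abs=1e-6)
        assert e.angle == pytest.approx(30, abs=1e-6)
        assert e.area == pytest.approx(np.pi * 200)
        assert e.axis_ratio == pytest.approx(0.5)

    def test_circle_has_unit_axis_ratio(self, rng):
        t = rng.uniform(0, 2 * np.pi, 300)
        pts = ellipse_points((0, 0), 7, 7, 0, t)
        e = gamut.fit_gamut_ellipse(pts)
        assert e.axis_ratio == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(20))
    def test_noisy_recovery_within_two_percent(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.uniform(0, 2 * np.pi, 1000)
        pts = ellipse_points((5, -3), 20, 10, 30, t) + rng.normal(0, 0.5, size=(1000, 2))
        e = gamut.fit_gamut_ellipse(pts)
        assert e.semi_major == pytest.approx(20, rel=0.02)
        assert e.semi_minor == pytest.approx(10, rel=0.02)
        assert e.area == pytest.approx(np.pi * 200, rel=0.02)
        assert abs(e.angle - 30) < 2.0

    def test_rotation_shifts_angle_only(self, rng):
        t = rng.uniform(0, 2 * np.pi, 500)
        pts = ellipse_points((0, 0), 15, 6, 20, t)
        rot = np.radians(40)
        R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        e1 = gamut.fit_gamut_ellipse(pts)
        e2 = gamut.fit_gamut_ellipse(pts @ R.T)
        assert e2.area == pytest.approx(e1.area, rel=1e-6)
        assert e2.axis_ratio == pytest.approx(e1.axis_ratio, rel=1e-6)
        assert e2.angle == pytest.approx((e1.angle + 40) % 180, abs=1e-6)

    def test_agrees_with_geometric_fit(self, rng):
        # skimage's EllipseModel minimises a different (geometric) criterion;
        # on dense low-noise data both fits land on the same ellipse
        from skimage.measure import EllipseModel

        t = rng.uniform(0, 2 * np.pi, 800)
        pts = ellipse_points((2, 1), 12, 8, 55, t) + rng.normal(0, 0.05, size=(800, 2))
        e = gamut.fit_gamut_ellipse(pts)
        m = EllipseModel.from_estimate(pts)
        sk_major, sk_minor = max(m.axis_lengths), min(m.axis_lengths)
        assert e.semi_major == pytest.approx(sk_major, rel=1e-3)
        assert e.semi_minor == pytest.approx(sk_minor, rel=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="5 distinct"):
            gamut.fit_gamut_ellipse(np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]]))


class TestSummary:
    def test_uniform_image_summary(self):
        img = np.full((8, 8, 3), [50.0, 5.0, 5.0])
        s = gamut.summarize_gamut(img)
        assert s.n_discernible == 1
        assert s.volume.degenerate and s.volume.volume == 0.0
        assert s.ellipse is None and "degenerate" in s.ellipse_error
        assert (s.mean_L, s.mean_a, s.mean_b) == (50.0, 5.0, 5.0)

    def test_composition_consistency(self, rng):
        img = rng.uniform([0, -50, -50], [100, 50, 50], size=(32, 32, 3))
        s = gamut.summarize_gamut(img)
        assert s.n_discernible == gamut.count_discernible_colors(img)
        assert s.volume.volume == gamut.gamut_volume(img).volume
        e = gamut.fit_gamut_ellipse(img)
        assert s.ellipse.semi_major == pytest.approx(e.semi_major)

    def test_pixel_shuffle_invariance(self, rng):
        img = rng.uniform(0, 100, size=(16, 16, 3))
        shuffled = rng.permutation(img.reshape(-1, 3)).reshape(img.shape)
        s1, s2 = gamut.summarize_gamut(img), gamut.summarize_gamut(shuffled)
        assert s1.n_discernible == s2.n_discernible
        assert s1.volume.volume == pytest.approx(s2.volume.volume)
        assert s1.to_row()["Area"] == pytest.approx(s2.to_row()["Area"])
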