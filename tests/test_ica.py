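import numpy as np
import pytest

from artpalette import ica
from artpalette.synthetic import generate_opponent_patches, opponent_axis_rgb


def two_source_mixture(seed, n=4000, A=None):
    rng = np.random.default_rng(seed)
    if A is None:
        A = np.array([[2.0, 0.5], [1.0, 1.5]])
    S = rng.uniform(-np.sqrt(3), np.sqrt(3), size=(n, 2))
    return S @ A.T, A


class TestSamplePatches:
    def test_whole_image_is_only_placement(self, rng):
        img = rng.uniform(0, 1, (8, 8, 3))
        ps = ica.sample_patches([img], n_per_image=1, p=8, seed=0)
        assert ps.n == 1
        assert np.array_equal(ps.vectors[0].reshape(8, 8, 3), img)

    def test_deterministic_for_fixed_seed(self, rng):
        imgs = [rng.uniform(0, 1, (32, 32, 3)) for _ in range(3)]
        a = ica.sample_patches(imgs, 20, p=8, seed=42)
        b = ica.sample_patches(imgs, 20, p=8, seed=42)
        assert np.array_equal(a.vectors, b.vectors)
        assert a.sources == b.sources

    def test_uniform_image_gives_identical_patches(self):
        img = np.full((32, 32, 3), 0.4)
        ps = ica.sample_patches([img], 100, p=8, seed=1)
        assert np.all(ps.vectors == ps.vectors[0])

    def test_small_image_skipped_with_warning(self, rng):
        small = rng.uniform(0, 1, (4, 4, 3))
        big = rng.uniform(0, 1, (16, 16, 3))
        with pytest.warns(UserWarning, match="skipped"):
            ps = ica.sample_patches([small, big], 10, p=8, seed=0)
        assert all(src[0] == 1 for src in ps.sources)

    def test_patches_fully_interior(self, rng):
        img = rng.uniform(0, 1, (20, 20, 3))
        ps = ica.sample_patches([img], 200, p=8, seed=3)
        for _, r, c in ps.sources:
            assert 0 <= r <= 12 and 0 <= c <= 12


class TestWhiten:
    def test_output_covariance_is_identity(self, rng):
        # anisotropic Gaussian with known covariance
        L = np.array([[3.0, 0.0, 0.0], [1.0, 2.0, 0.0], [0.5, 0.5, 1.0]])
        X = rng.normal(size=(5000, 3)) @ L.T
        w = ica.whiten(ica.PatchSet(vectors=X, p=1))
        cov = w.vectors.T @ w.vectors / w.vectors.shape[0]
        assert np.abs(cov - np.eye(3)).max() < 1e-6

    def test_already_white_data_stays_white(self, rng):
        X = rng.normal(size=(6000, 4))
        w = ica.whiten(ica.PatchSet(vectors=X, p=1))
        cov = w.vectors.T @ w.vectors / w.vectors.shape[0]
        assert np.abs(cov - np.eye(4)).max() < 1e-6
        # the whitening map of near-white data is near-orthogonal
        WWt = w.whitening @ w.whitening.T
        assert np.abs(WWt - np.diag(np.diag(WWt))).max() < 0.1

    def test_dewhitening_inverts_whitening(self, rng):
        X = rng.normal(size=(2000, 5)) * [5, 3, 2, 1, 0.5]
        w = ica.whiten(ica.PatchSet(vectors=X, p=1))
        rec = w.vectors @ w.dewhitening.T + w.mean
        assert np.allclose(rec, X, atol=1e-8)

    def test_identical_patches_rejected(self):
        X = np.tile(np.arange(4.0), (50, 1))
        with pytest.raises(ValueError, match="zero-variance"):
            ica.whiten(ica.PatchSet(vectors=X, p=1))

    def test_rank_deficient_data_reduces_dimension(self, rng):
        base = rng.normal(size=(500, 2))
        X = np.column_stack([base, base @ np.array([[1.0], [2.0]])])  # rank 2 in 3-D
        with pytest.warns(UserWarning, match="rank-deficient"):
            w = ica.whiten(ica.PatchSet(vectors=X, p=1))
        assert w.vectors.shape[1] == 2

    def test_needs_more_patches_than_dimensions(self, rng):
        X = rng.normal(size=(10, 12))
        with pytest.raises(ValueError, match="more patches"):
            ica.whiten(ica.PatchSet(vectors=X, p=2))


class TestFitICA:
    @pytest.mark.parametrize("seed", range(20))
    def test_recovers_planted_two_source_mixture(self, seed):
        X, A = two_source_mixture(seed)
        res = ica.fit_ica(ica.whiten(ica.PatchSet(vectors=X, p=1)), seed=seed, p=1)
        assert res.converged
        est = np.column_stack([b.vector / np.linalg.norm(b.vector) for b in res.bases])
        true = A / np.linalg.norm(A, axis=0)
        # sign/permutation-invariant angular match of mixing directions
        for t in true.T:
            cosang = np.max(np.abs(est.T @ t))
            assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 3.0

    def test_gaussian_data_flagged_unreliable(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4000, 2)) @ np.array([[2.0, 0.5], [1.0, 1.5]]).T
        res = ica.fit_ica(ica.whiten(ica.PatchSet(vectors=X, p=1)), seed=0, p=1)
        assert not res.reliable  # non-Gaussianity is required for identifiability

    def test_mixing_reconstructs_centred_data(self):
        X, _ = two_source_mixture(7)
        w = ica.whiten(ica.PatchSet(vectors=X, p=1))
        res = ica.fit_ica(w, seed=7, p=1)
        A = np.column_stack([b.vector for b in res.bases])
        S = np.linalg.pinv(A) @ (X - X.mean(axis=0)).T
        assert np.abs((A @ S).T + X.mean(axis=0) - X).max() < 1e-10

    def test_deterministic_for_fixed_seed(self):
        X, _ = two_source_mixture(3)
        w = ica.whiten(ica.PatchSet(vectors=X, p=1))
        r1 = ica.fit_ica(w, seed=5, p=1)
        r2 = ica.fit_ica(w, seed=5, p=1)
        assert np.array_equal(
            np.column_stack([b.vector for b in r1.bases]),
            np.column_stack([b.vector for b in r2.bases]),
        )


class TestOrderAndNormalize:
    def _basis(self, vec):
        v = np.asarray(vec, dtype=float)
        return ica.ICABasis(vector=v, energy=float(np.linalg.norm(v)), p=1)

    def test_energy_ordering(self):
        bases = [self._basis([3, 0, 0]), self._basis([1, 0, 0]), self._basis([0, 2, 0])]
        out = ica.order_and_normalize(bases)
        assert [b.energy for b in out] == [3.0, 2.0, 1.0]
        assert [b.rank for b in out] == [1, 2, 3]

    def test_unit_norms_after_normalisation(self, rng):
        bases = [self._basis(rng.normal(size=6)) for _ in range(5)]
        out = ica.order_and_normalize(bases)
        for b in out:
            assert np.linalg.norm(b.vector) == pytest.approx(1.0, abs=1e-12)

    def test_stable_order_for_equal_energies(self):
        bases = [self._basis([2, 0, 0]), self._basis([0, 2, 0]), self._basis([0, 0, 1])]
        out = ica.order_and_normalize(bases)
        assert np.allclose(out[0].vector, [1, 0, 0])
        assert np.allclose(out[1].vector, [0, 1, 0])


class TestBasisColorDirection:
    def _basis_along(self, axis, p=8, seed=0):
        rng = np.random.default_rng(seed)
        profile = rng.normal(size=(p, p, 1))
        patch = profile * np.asarray(axis, dtype=float)
        return ica.ICABasis(vector=patch.reshape(-1), energy=1.0, p=p)

    def test_red_axis_maps_to_30_degrees(self):
        assert ica.basis_color_direction(self._basis_along([1, 0, 0])) == pytest.approx(30.0, abs=1e-8)

    def test_achromatic_axis_flagged(self):
        assert ica.basis_color_direction(self._basis_along([1, 1, 1])) is None

    def test_blue_and_yellow_fold_to_90(self):
        blue = ica.basis_color_direction(self._basis_along([0, 0, 1]))
        yellow = ica.basis_color_direction(self._basis_along([1, 1, 0]))
        assert blue == pytest.approx(90.0, abs=1e-8)
        assert yellow == pytest.approx(90.0, abs=1e-8)

    def test_sign_flip_invariance(self):
        b = self._basis_along([0.2, 0.9, -0.1], seed=4)
        flipped = ica.ICABasis(vector=-b.vector, energy=b.energy, p=b.p)
        assert ica.basis_color_direction(b) == pytest.approx(
            ica.basis_color_direction(flipped), abs=1e-9
        )

    def test_zero_basis_flagged(self):
        b = ica.ICABasis(vector=np.zeros(8 * 8 * 3), energy=0.0, p=8)
        assert ica.basis_color_direction(b) is None


class TestDirectionHistogram:
    def test_counts_in_expected_bins(self):
        hist = ica.direction_histogram([30.0, 30.0, 90.0], bin_width=10)
        assert hist.counts[3] == 2 and hist.counts[9] == 1
        assert hist.counts.sum() == 3

    def test_achromatic_entries_excluded_and_reported(self):
        hist = ica.direction_histogram([45.0, None, None], bin_width=10)
        assert hist.counts.sum() == 1
        assert hist.n_achromatic == 2

    def test_unfolded_covers_full_circle(self):
        hist = ica.direction_histogram([350.0], bin_width=10, folded=False)
        assert hist.bin_edges[-1] == 360.0
        assert hist.counts[-1] == 1

    def test_planted_modes_recovered(self):
        rng = np.random.default_rng(0)
        angles = []
        for mode in (30.0, 90.0, 130.0):
            angles.extend((rng.normal(mode, 3.0, 30) % 180.0).tolist())
        hist = ica.direction_histogram(angles, bin_width=10)
        top3 = np.argsort(hist.counts)[-3:]
        mode_bins = np.array([3, 9, 13])
        for b in top3:
            assert np.min(np.abs(mode_bins - b)) <= 1
        # and the bulk of each mode's mass sits within one bin of its centre
        for m, b in zip((30.0, 90.0, 130.0), mode_bins):
            assert hist.counts[max(b - 1, 0) : b + 2].sum() >= 25


class TestEndToEndDirectionRecovery:
    @pytest.mark.parametrize("angle", [30.0, 90.0, 130.0])
    def test_planted_angle_recovered(self, angle):
        ps = generate_opponent_patches(2000, p=8, planted_angle=angle, seed=0)
        w = ica.whiten(ps, n_components=6)
        res = ica.fit_ica(w, seed=0, p=8)
        bases = ica.order_and_normalize(res.bases)
        directions = [ica.basis_color_direction(b) for b in bases]
        dominant = next(d for d in directions if d is not None)
        err = min(abs(dominant - angle), 180 - abs(dominant - angle))
        assert err <= 10.0

    def test_achromatic_patch_set_all_flagged(self, rng):
        # gradient patches along the grey axis only
        profile = rng.normal(size=(300, 64, 1))
        patches = (profile * np.ones(3) / np.sqrt(3)).reshape(300, -1) * 0.1 + 0.5
        ps = ica.PatchSet(vectors=patches, p=8)
        w = ica.whiten(ps, n_components=4)
        res = ica.fit_ica(w, seed=0, p=8)
        assert all(ica.basis_color_direction(b) is None for b in res.bases)

    def test_opponent_axis_projection_exact(self):
        from artpalette.colorspace import rgb_to_opponent

        for angle in (0.0, 30.0, 90.0, 130.0):
            d = opponent_axis_rgb(angle)
            # the transform is linear so direction vectors project directly
            rg = (d[0] - d[1]) / np.sqrt(2)
            by = (d[0] + d[1] - 2 * d[2]) / np.sqrt(6)
            assert np.degrees(np.arctan2(by, rg)) % 360 == pytest.approx(angle % 360, abs=1e-9)
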