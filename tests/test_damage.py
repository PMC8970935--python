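import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from kinetrack import damage, synthetic
from kinetrack.damage import ContourModel


def circle_contour(center, radius, n=40, a=0.1, beta=1.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.c_[center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
    return ContourModel(points=pts, a=a, beta=beta)


def blurred_disc(shape=(64, 64), center=(32, 32), radius=12, sigma=2.0):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    disc = ((rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2)
    return gaussian_filter(disc.astype(float), sigma)


class TestSnakeEnergy:
    def test_zero_weights_zero_energy(self, rng):
        contour = circle_contour((16, 16), 5, a=0.0, beta=0.0)
        assert damage.snake_energy(contour, rng.random((32, 32))) == 0.0

    def test_straight_segment_internal_energy_hand_sum(self):
        """Evenly spaced square loop on a constant image: E = a * sum d_t^2."""
        pts = [(10.0, 10.0 + 2 * i) for i in range(5)]   # right along a row
        pts += [(10.0 + 2 * i, 18.0) for i in range(1, 5)]
        pts += [(18.0, 18.0 - 2 * i) for i in range(1, 5)]
        pts += [(18.0 - 2 * i, 10.0) for i in range(1, 4)]
        contour = ContourModel(np.array(pts), a=1.0, beta=0.0)
        flat = np.full((32, 32), 0.5)
        # hand summation: 16 edges of length 2, plus corner curvature terms
        d1 = np.roll(contour.points, -1, axis=0) - contour.points
        d2 = np.roll(contour.points, -1, axis=0) - 2 * contour.points \
            + np.roll(contour.points, 1, axis=0)
        expected = (d1 ** 2).sum() + (d2 ** 2).sum()
        assert (d1 ** 2).sum() == pytest.approx(16 * 4.0)
        assert damage.snake_energy(contour, flat) == pytest.approx(expected)

    def test_interior_segment_curvature_free(self):
        """Collinear evenly spaced points contribute no curvature energy."""
        pts = np.array([(5.0, 5.0), (5.0, 8.0), (5.0, 11.0), (5.0, 14.0)])
        d2 = np.roll(pts, -1, axis=0) - 2 * pts + np.roll(pts, 1, axis=0)
        assert np.all(d2[1:3] == 0.0)

    def test_edge_contour_has_lower_energy_than_flat_region(self):
        gray = blurred_disc()
        on_edge = circle_contour((32, 32), 12, a=0.0, beta=1.0)
        off_edge = circle_contour((32, 32), 3, a=0.0, beta=1.0)
        assert damage.snake_energy(on_edge, gray) \
            < damage.snake_energy(off_edge, gray)

    def test_contour_outside_frame_rejected(self):
        contour = circle_contour((2, 2), 5)
        with pytest.raises(ValueError, match="outside"):
            damage.snake_energy(contour, np.zeros((16, 16)))


class TestLocalizeDamage:
    def test_descent_never_increases_energy(self):
        gray = blurred_disc()
        init = circle_contour((32, 32), 15, a=0.01, beta=5.0)
        e0 = damage.snake_energy(init, gray)
        out = damage.localize_damage(gray, init, max_iter=50)
        assert damage.snake_energy(out, gray) <= e0 + 1e-9

    def test_fixed_point_returned_unchanged(self):
        """A contour already at its energy minimum does not move."""
        gray = blurred_disc()
        init = circle_contour((32, 32), 15, a=0.01, beta=5.0)
        relaxed = damage.localize_damage(gray, init, max_iter=200)
        again = damage.localize_damage(gray, relaxed, max_iter=200)
        np.testing.assert_array_equal(again.points, relaxed.points)

    def test_circle_contracts_onto_disc_boundary(self):
        gray = blurred_disc(radius=12, sigma=2.0)
        init = circle_contour((32, 32), 15, a=0.01, beta=5.0)
        out = damage.localize_damage(gray, init, max_iter=200)
        radii = np.hypot(out.points[:, 0] - 32, out.points[:, 1] - 32)
        assert np.abs(radii - 12).mean() <= 1.0


class TestSubspace:
    def test_default_retention_is_sixty_percent(self):
        samples, _ = synthetic.make_damage_gallery(3, 4, seed=0)
        sub = damage.fit_subspace(samples)
        assert sub.retention == 0.60
        assert sub.n_components == len(sub.eigenvalues)

    def test_retention_truncates_at_cumulative_mass(self, rng):
        # anisotropic Gaussian cloud with known spectrum
        scales = np.array([5.0, 2.0, 1.0, 0.5, 0.1])
        X = rng.standard_normal((200, 5)) * scales
        samples = [x.reshape(1, 5) for x in X]
        sub = damage.fit_subspace(samples, retention=0.6)
        full = np.linalg.eigvalsh(np.cov(X.T))[::-1]
        cum = np.cumsum(full) / full.sum()
        expected_k = int(np.searchsorted(cum, 0.6 - 1e-12) + 1)
        assert sub.n_components == expected_k

    def test_rank_one_variation_recovers_direction(self, rng):
        base = rng.random((6, 6))
        direction = rng.standard_normal(36)
        direction /= np.linalg.norm(direction)
        samples = [base + t * direction.reshape(6, 6)
                   for t in np.linspace(-1, 1, 9)]
        sub = damage.fit_subspace(samples, retention=0.99)
        assert sub.n_components == 1
        cos = abs(float(sub.eigenvectors[:, 0] @ direction))
        assert cos >= 0.999

    def test_identical_samples_give_empty_subspace_with_warning(self, rng):
        img = rng.random((4, 4))
        with pytest.warns(UserWarning, match="identical"):
            sub = damage.fit_subspace([img.copy() for _ in range(5)])
        assert sub.n_components == 0

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            damage.fit_subspace([rng.random((4, 4))])

    def test_eigenvectors_orthonormal(self):
        samples, _ = synthetic.make_damage_gallery(3, 6, seed=1)
        sub = damage.fit_subspace(samples, retention=0.95)
        G = sub.eigenvectors.T @ sub.eigenvectors
        np.testing.assert_allclose(G, np.eye(sub.n_components), atol=1e-8)

    def test_reconstruction_error_decreases_with_retention(self, rng):
        samples, _ = synthetic.make_damage_gallery(3, 8, seed=2)
        query = samples[0]
        errs = []
        for retention in (0.3, 0.6, 0.9, 0.999):
            sub = damage.fit_subspace(samples[1:], retention)
            y = damage.project(query, sub)
            recon = sub.mean + sub.eigenvectors @ y
            errs.append(np.linalg.norm(query.ravel() - recon))
        assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))

    def test_subspace_roundtrip(self, tmp_path):
        samples, _ = synthetic.make_damage_gallery(2, 3, seed=0)
        sub = damage.fit_subspace(samples)
        damage.save_subspace(sub, tmp_path / "sub.npz")
        loaded = damage.load_subspace(tmp_path / "sub.npz")
        np.testing.assert_array_equal(loaded.eigenvectors, sub.eigenvectors)
        assert loaded.image_shape == sub.image_shape


@pytest.fixture(scope="module")
def fitted():
    samples, labels = synthetic.make_damage_gallery(3, 12, seed=3)
    train = [i for i in range(36) if i % 12 < 10]
    sub = damage.fit_subspace([samples[i] for i in train], retention=0.9)
    gallery = damage.build_gallery([samples[i] for i in train],
                                   labels[train], sub)
    return samples, labels, train, sub, gallery


class TestProjectClassify:
    def test_mean_projects_to_zero(self, fitted):
        _, _, _, sub, _ = fitted
        y = damage.project(sub.mean.reshape(sub.image_shape), sub)
        np.testing.assert_allclose(y, 0.0, atol=1e-10)

    def test_mean_plus_eigenvector_gives_unit_coefficient(self, fitted):
        _, _, _, sub, _ = fitted
        x = sub.mean + sub.eigenvectors[:, 0]
        y = damage.project(x.reshape(sub.image_shape), sub)
        expected = np.zeros(sub.n_components)
        expected[0] = 1.0
        np.testing.assert_allclose(y, expected, atol=1e-8)

    def test_projection_is_contractive(self, fitted, rng):
        _, _, _, sub, _ = fitted
        for _ in range(20):
            x = rng.random(sub.image_shape)
            y = damage.project(x, sub)
            assert np.linalg.norm(y) <= np.linalg.norm(x.ravel() - sub.mean) + 1e-12

    def test_shape_mismatch_rejected(self, fitted):
        _, _, _, sub, _ = fitted
        with pytest.raises(ValueError, match="shape"):
            damage.project(np.zeros((3, 3)), sub)

    def test_query_equal_to_gallery_entry(self, fitted):
        samples, labels, train, sub, gallery = fitted
        label, dist = damage.classify_nn(
            damage.project(samples[train[0]], sub), gallery)
        assert label == labels[train[0]]
        assert dist == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_nearest_neighbour(self, fitted, rng):
        _, _, _, sub, gallery = fitted
        for _ in range(100):
            q = rng.standard_normal(sub.n_components)
            label, dist = damage.classify_nn(q, gallery)
            best_i, best_d = None, np.inf
            for i, g in enumerate(gallery.coefficients):
                d = float(np.sqrt(((q - g) ** 2).sum()))
                if d < best_d:
                    best_i, best_d = i, d
            assert label == gallery.labels[best_i]
            assert dist == best_d

    def test_tie_breaks_to_lower_index(self):
        gallery = damage.Gallery(coefficients=np.array([[1.0], [-1.0]]),
                                 labels=np.array([7, 9]))
        label, _ = damage.classify_nn(np.array([0.0]), gallery)
        assert label == 7

    def test_empty_gallery_rejected(self):
        gallery = damage.Gallery(coefficients=np.empty((0, 2)),
                                 labels=np.empty(0))
        with pytest.raises(ValueError, match="empty"):
            damage.classify_nn(np.zeros(2), gallery)


def test_held_out_accuracy_on_default_gallery():
    """3 classes, 10 train + 5 test per class, separation 5x noise."""
    samples, labels = synthetic.make_damage_gallery(3, 15, seed=0)
    train = [i for i in range(45) if i % 15 < 10]
    test = [i for i in range(45) if i % 15 >= 10]
    sub = damage.fit_subspace([samples[i] for i in train])
    gallery = damage.build_gallery([samples[i] for i in train],
                                   labels[train], sub)
    hits = sum(damage.classify_nn(damage.project(samples[i], sub), gallery)[0]
               == labels[i] for i in test)
    assert hits / len(test) >= 0.9
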