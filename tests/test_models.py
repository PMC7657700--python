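"""Baseline region models: fitted statistics, evolution forces, and the
finite-difference energy-gradient oracle.

The oracle is the primary correctness check: on small random instances
the implemented data force must equal the negative derivative of the
discretized data energy with respect to each phi pixel (statistics held
frozen, as in the alternating-minimization scheme)."""

import numpy as np
import pytest

from acmseg.core import dirac_eps, heaviside_eps, initialize_phi
from acmseg.models import (
    DegenerateContourError,
    cv_data_force,
    cv_energy,
    cv_evolve_step,
    cv_means,
    lbf_data_force,
    lbf_energy,
    lbf_means,
    min_data_force,
    min_energy,
    min_means,
)
from acmseg.params import ModelParams


def fd_gradient(energy_fn, phi, step=1e-6):
    """Central finite-difference gradient of a scalar energy in phi."""
    g = np.zeros_like(phi)
    it = np.nditer(phi, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        up = phi.copy()
        up[idx] += step
        dn = phi.copy()
        dn[idx] -= step
        g[idx] = (energy_fn(up) - energy_fn(dn)) / (2 * step)
    return g


def random_instance(rng, n=8):
    image = rng.uniform(0.05, 0.95, size=(n, n))
    phi = rng.uniform(-3, 3, size=(n, n))
    return image, phi


def relerr(a, b):
    return np.linalg.norm(a - b) / max(np.linalg.norm(b), 1e-300)


class TestChanVese:
    def test_constant_image_means_equal(self, rng, small_params):
        phi = rng.uniform(-2, 2, size=(10, 10))
        e1, e2 = cv_means(np.full((10, 10), 0.37), phi, 1.0)
        assert e1 == pytest.approx(0.37)
        assert e2 == pytest.approx(0.37)

    def test_sharp_partition_limit(self):
        image = np.full((20, 20), 0.2)
        image[5:15, 5:15] = 0.8
        phi = np.where(image > 0.5, 5.0, -5.0)
        e1, e2 = cv_means(image, phi, 1e-4)
        assert e1 == pytest.approx(0.8, abs=1e-3)
        assert e2 == pytest.approx(0.2, abs=1e-3)

    def test_means_match_bruteforce_weighted_sums(self, rng):
        image = rng.uniform(0, 1, size=(5, 5))
        phi = rng.uniform(-2, 2, size=(5, 5))
        eps = 1.3
        h = heaviside_eps(phi, eps)
        e1, e2 = cv_means(image, phi, eps)
        num1 = den1 = num2 = den2 = 0.0
        for i in range(5):
            for j in range(5):
                num1 += image[i, j] * h[i, j]
                den1 += h[i, j]
                num2 += image[i, j] * (1 - h[i, j])
                den2 += 1 - h[i, j]
        assert e1 == pytest.approx(num1 / den1)
        assert e2 == pytest.approx(num2 / den2)

    def test_collapsed_contour_raises(self):
        phi = np.full((10, 10), 1e9)
        with pytest.raises(DegenerateContourError):
            cv_means(np.random.rand(10, 10), phi, 1e-6)

    def test_negating_phi_swaps_means(self, rng):
        image, phi = random_instance(rng, 12)
        e1, e2 = cv_means(image, phi, 1.0)
        e1n, e2n = cv_means(image, -phi, 1.0)
        assert e1 == pytest.approx(e2n) and e2 == pytest.approx(e1n)

    def test_data_force_sign_expels_mismatched_pixel(self, small_params):
        # pixel matching the outside mean but not the inside mean is
        # pushed toward the outside (negative force)
        force = cv_data_force(np.array([[0.2]]), e1=0.8, e2=0.2, params=small_params)
        assert force[0, 0] < 0

    def test_constant_image_step_reduces_to_regularization(self, small_params):
        image = np.full((12, 12), 0.5)
        region = np.zeros((12, 12), bool)
        region[4:8, 4:8] = True
        phi = initialize_phi((12, 12), region, 2.0)
        p = small_params.with_updates(nu=0.0, mu=0.0)
        stepped = cv_evolve_step(image, phi, p)
        assert np.allclose(stepped, phi)  # no data, no regularization

    def test_force_matches_energy_gradient(self, rng, small_params):
        p = small_params.with_updates(nu=0.0, mu=0.0)
        for _ in range(5):
            image, phi = random_instance(rng)
            e1, e2 = cv_means(image, phi, p.epsilon)
            force = dirac_eps(phi, p.epsilon) * cv_data_force(image, e1, e2, p)
            fd = fd_gradient(lambda q: cv_energy(image, q, e1, e2, p, data_only=True), phi)
            assert relerr(force, -fd) < 1e-4


class TestLBF:
    def test_constant_image_local_means(self, rng):
        phi = rng.uniform(-2, 2, size=(16, 16))
        h1, h2 = lbf_means(np.full((16, 16), 0.6), phi, sigma=2.0, epsilon=1.0)
        assert np.allclose(h1, 0.6)
        assert np.allclose(h2, 0.6)

    def test_local_means_track_bias_ramp(self):
        # a ramped two-level image: local means follow the ramp while
        # the global mean cannot
        n = 64
        ramp = np.linspace(0.5, 1.0, n)[None, :] * np.ones((n, n))
        image = np.where(np.arange(n)[:, None] < n // 2, 0.8, 0.3) * ramp
        phi = np.where(np.arange(n)[:, None] < n // 2, 2.0, -2.0) * np.ones((n, n))
        h1, _ = lbf_means(image, phi, sigma=4.0, epsilon=1.0)
        e1, _ = cv_means(image, phi, 1.0)
        inside = (np.arange(n)[:, None] < n // 2) & np.ones((n, n), bool)
        local_err = np.abs(h1 - image)[inside].mean()
        global_err = np.abs(e1 - image)[inside].mean()
        assert local_err < 0.5 * global_err

    def test_large_sigma_approaches_global_means(self, rng):
        image = rng.uniform(0.2, 0.8, size=(32, 32))
        phi = rng.uniform(-2, 2, size=(32, 32))
        h1, h2 = lbf_means(image, phi, sigma=32.0, epsilon=1.0)
        e1, e2 = cv_means(image, phi, 1.0)
        assert np.abs(h1 - e1).max() / e1 < 0.05
        assert np.abs(h2 - e2).max() / e2 < 0.05

    def test_zero_force_when_image_equals_both_means(self, small_params):
        image = np.full((10, 10), 0.5)
        h = np.full((10, 10), 0.5)
        force = lbf_data_force(image, h, h, small_params)
        assert np.allclose(force, 0.0, atol=1e-9)

    def test_force_matches_energy_gradient(self, rng, small_params):
        p = small_params
        for _ in range(5):
            image, phi = random_instance(rng)
            h1, h2 = lbf_means(image, phi, p.sigma, p.epsilon)
            force = dirac_eps(phi, p.epsilon) * lbf_data_force(image, h1, h2, p)
            fd = fd_gradient(
                lambda q: lbf_energy(image, q, h1, h2, p, data_only=True), phi)
            assert relerr(force, -fd) < 1e-4


class TestGlobalDivision:
    def test_two_level_inside_split(self):
        # inside holds values {0.4 x3, 0.2 x2}: e1 = 0.32 and the split
        # means recover the two levels
        image = np.full((5, 5), 0.9)
        image[0, :5] = [0.4, 0.4, 0.4, 0.2, 0.2]
        phi = np.full((5, 5), -50.0)
        phi[0, :] = 50.0
        g11, g12, g21, g22, e1, e2 = min_means(image, phi, epsilon=1e-3)
        assert e1 == pytest.approx(0.32, abs=1e-3)
        assert g11 == pytest.approx(0.4, abs=1e-3)
        assert g12 == pytest.approx(0.2, abs=1e-3)

    def test_constant_region_falls_back_to_parent_mean(self):
        image = np.full((8, 8), 0.5)
        phi = np.where(np.arange(8)[:, None] < 4, 30.0, -30.0) * np.ones((8, 8))
        g11, g12, g21, g22, e1, e2 = min_means(image, phi, 1.0)
        # smooth split of a constant region keeps both sub-means at the
        # parent mean (weights are symmetric around I - e = 0)
        assert g11 == pytest.approx(e1) and g12 == pytest.approx(e1)
        assert g21 == pytest.approx(e2) and g22 == pytest.approx(e2)

    def test_ordering_invariant(self, rng):
        for _ in range(10):
            image, phi = random_instance(rng, 12)
            g11, g12, g21, g22, _, _ = min_means(image, phi, 1.0)
            assert g11 >= g12 - 1e-12
            assert g21 >= g22 - 1e-12

    def test_negating_phi_swaps_pairs(self, rng):
        image, phi = random_instance(rng, 10)
        a = min_means(image, phi, 1.0)
        b = min_means(image, -phi, 1.0)
        assert a[0] == pytest.approx(b[2]) and a[1] == pytest.approx(b[3])
        assert a[2] == pytest.approx(b[0]) and a[3] == pytest.approx(b[1])
        assert a[4] == pytest.approx(b[5]) and a[5] == pytest.approx(b[4])

    def test_force_matches_energy_gradient(self, rng, small_params):
        p = small_params
        for _ in range(5):
            image, phi = random_instance(rng)
            g11, g12, g21, g22, e1, e2 = min_means(image, phi, p.epsilon)
            force = dirac_eps(phi, p.epsilon) * min_data_force(
                image, g11, g12, g21, g22, e1, e2, p)
            fd = fd_gradient(
                lambda q: min_energy(image, q, g11, g12, g21, g22, e1, e2, p,
                                     data_only=True), phi)
            assert relerr(force, -fd) < 1e-4
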