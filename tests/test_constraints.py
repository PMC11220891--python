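"""Projection operators: modulus constraint (κ machinery) and support."""

import numpy as np
import pytest

from braggfxs.constraints import (
    EigenBasis,
    ModulusConstraint,
    build_support_mask,
    eigendecompose_b,
    kappa_expand,
    kappa_inverse,
    modulus_project,
    scale_kappa,
    support_project,
)
from braggfxs.harmonics import (
    HarmonicCoefficients,
    HarmonicOrderMatrices,
    SphericalGrid,
    SphericalIntensity,
    b_from_coeffs,
    sht_forward,
    sht_inverse,
)
from braggfxs.lattice import BraggPeakList
from braggfxs.metrics import r_factor, extract_peak_intensities
from braggfxs.synthetic import make_toy_crystal


@pytest.fixture(scope="module")
def unit_bundle():
    """Toy bundle rescaled so the gridded intensity is O(1)."""
    b = make_toy_crystal(seed=5)
    scale = np.abs(b.intensity.values).max()
    intensity = SphericalIntensity(b.intensity.values / scale, b.grid)
    bmat = HarmonicOrderMatrices(b.b.values / scale ** 2, b.b.q_max)
    return b, intensity, bmat


class TestEigendecompose:
    def test_identity_b(self):
        b = HarmonicOrderMatrices(
            np.repeat(np.eye(4)[:, :, None], 3, axis=2), 1.0
        )
        basis = eigendecompose_b(b)
        assert np.allclose(basis.eigvals, 1.0)
        for l in range(3):
            u = basis.eigvecs[l]
            # a signed permutation of the standard basis (eigenvalues are
            # degenerate, so the column order is not fixed)
            assert np.allclose(u @ u.T, np.eye(4), atol=1e-12)
            assert np.allclose(np.abs(u).max(axis=0), 1.0, atol=1e-12)
            assert np.allclose((u * basis.eigvals[l]) @ u.T, np.eye(4),
                               atol=1e-12)

    def test_rank_one(self, rng):
        v = rng.normal(size=5)
        b = HarmonicOrderMatrices(np.outer(v, v)[:, :, None], 1.0)
        basis = eigendecompose_b(b)
        assert basis.eigvals[0, 0] == pytest.approx(v @ v, rel=1e-12)
        assert np.abs(basis.eigvals[0, 1:]).max() < 1e-10 * (v @ v)
        u = basis.eigvecs[0][:, 0]
        # deterministic sign: largest-magnitude component positive
        assert u[np.argmax(np.abs(u))] > 0
        assert np.allclose(np.abs(u), np.abs(v / np.linalg.norm(v)), atol=1e-12)

    def test_reconstruction_of_random_psd(self, rng):
        a = rng.normal(size=(6, 6, 4))
        b = HarmonicOrderMatrices(np.einsum("ikl,jkl->ijl", a, a), 1.0)
        basis = eigendecompose_b(b)
        for l in range(4):
            rebuilt = (basis.eigvecs[l] * basis.eigvals[l]) @ basis.eigvecs[l].T
            assert np.abs(rebuilt - b.values[:, :, l]).max() < 1e-10 * max(
                1.0, np.abs(b.values[:, :, l]).max()
            )
            assert np.allclose(
                basis.eigvecs[l].T @ basis.eigvecs[l], np.eye(6), atol=1e-10
            )

    def test_asymmetric_rejected(self, rng):
        vals = rng.normal(size=(4, 4, 2))
        with pytest.raises(ValueError, match="symmetric"):
            eigendecompose_b(HarmonicOrderMatrices(vals, 1.0))


class TestKappa:
    def _setup(self, rng, n_q=5, n_theta=8):
        grid = SphericalGrid(n_q, n_theta, 1.0)
        n_l = grid.n_l
        coeffs = HarmonicCoefficients(
            rng.normal(size=(n_q, n_l, 2 * n_l - 1)), grid
        )
        for l in range(n_l):
            coeffs.values[:, l, : n_l - 1 - l] = 0
            coeffs.values[:, l, n_l + l:] = 0
        return grid, coeffs

    def test_aligned_coefficients_single_entry(self, rng):
        grid, coeffs = self._setup(rng)
        basis = eigendecompose_b(b_from_coeffs(coeffs))
        u = basis.eigvecs[2][:, 1]
        aligned = np.zeros_like(coeffs.values)
        aligned[:, 2, 4] = 2.0 * u
        k = kappa_expand(HarmonicCoefficients(aligned, grid), basis)
        assert k.values[2, 4, 1] == pytest.approx(2.0, rel=1e-10)
        rest = k.values.copy()
        rest[2, 4, 1] = 0
        assert np.abs(rest).max() < 1e-10

    def test_full_rank_round_trip(self, rng):
        grid, coeffs = self._setup(rng)
        basis = eigendecompose_b(b_from_coeffs(coeffs))
        back = kappa_inverse(kappa_expand(coeffs, basis), basis, grid)
        assert np.abs(back.values - coeffs.values).max() < 1e-10

    def test_rank_deficient_projects_onto_span(self, rng):
        grid, coeffs = self._setup(rng)
        full = eigendecompose_b(b_from_coeffs(coeffs))
        trunc = EigenBasis(full.eigvecs[:, :, :2], full.eigvals[:, :2])
        back = kappa_inverse(kappa_expand(coeffs, trunc), trunc, grid)
        for l in range(grid.n_l):
            u = trunc.eigvecs[l]
            proj = u @ u.T  # direct projector oracle P = UUᵀ
            expect = np.einsum("pq,qm->pm", proj, coeffs.values[:, l, :])
            assert np.abs(back.values[:, l, :] - expect).max() < 1e-10


class TestScaleKappa:
    def test_zero_eigenvalue_rows_zeroed(self, rng):
        basis = EigenBasis(np.eye(3)[None].repeat(2, 0),
                           np.array([[1.0, 0.0, 4.0]] * 2))
        from braggfxs.constraints import KappaCoefficients

        k = KappaCoefficients(rng.normal(size=(2, 3, 3)))
        out = scale_kappa(k, basis)
        assert not out.values[:, :, 1].any()

    def test_self_consistent_coefficients_fixed(self, rng):
        """With B built from the coefficients, ‖K‖² = λ so scaling is inert."""
        grid = SphericalGrid(5, 8, 1.0)
        n_l = grid.n_l
        vals = rng.normal(size=(5, n_l, 2 * n_l - 1))
        for l in range(n_l):
            vals[:, l, : n_l - 1 - l] = 0
            vals[:, l, n_l + l:] = 0
        coeffs = HarmonicCoefficients(vals, grid)
        basis = eigendecompose_b(b_from_coeffs(coeffs))
        k = kappa_expand(coeffs, basis)
        out = scale_kappa(k, basis)
        assert np.abs(out.values - k.values).max() < 1e-8 * np.abs(k.values).max()

    def test_zero_input_stays_zero(self):
        basis = EigenBasis(np.eye(3)[None], np.array([[2.0, 1.0, 0.5]]))
        from braggfxs.constraints import KappaCoefficients

        out = scale_kappa(KappaCoefficients(np.zeros((1, 1, 3))), basis)
        assert not out.values.any()
        assert np.isfinite(out.values).all()


class TestModulusProject:
    def test_fixed_point_on_self_consistent_fixture(self, unit_bundle):
        """P_m leaves the true intensity unchanged when its own harmonic
        order matrices generated the eigenbasis."""
        _, intensity, bmat = unit_bundle
        pm = ModulusConstraint.from_b(bmat)
        out = pm(intensity)
        assert np.abs(out.values - intensity.values).max() < 1e-6

    def test_zero_basis_annihilates_band_limited_input(self, rng):
        grid = SphericalGrid(2, 8, 1.0)
        n_l = grid.n_l
        c = np.zeros((2, n_l, 2 * n_l - 1))
        c[:, 1, n_l - 1] = 1.3
        field = sht_inverse(HarmonicCoefficients(c, grid))
        zero_b = HarmonicOrderMatrices(np.zeros((2, 2, n_l)), 1.0)
        out = modulus_project(field, eigendecompose_b(zero_b))
        assert np.abs(out.values).max() < 1e-10

    def test_above_band_limit_mode_passes_through_residual(self):
        """Content at the first excluded degree l = n_l survives exactly."""
        from scipy.special import gammaln, lpmv

        grid = SphericalGrid(2, 16, 1.0)
        l, m = grid.n_l, 3
        norm = np.exp(0.5 * (np.log(2 * l + 1.0) - np.log(2.0)
                             + gammaln(l - m + 1) - gammaln(l + m + 1)))
        lam = (-1.0) ** m * norm * lpmv(m, l, np.cos(grid.thetas))
        mode = lam[:, None] * np.cos(m * grid.phis)[None, :] / np.sqrt(np.pi)
        field = SphericalIntensity(
            np.broadcast_to(mode, grid.shape).copy(), grid
        )
        zero_b = HarmonicOrderMatrices(np.zeros((2, 2, grid.n_l)), 1.0)
        out = modulus_project(field, eigendecompose_b(zero_b))
        assert np.abs(out.values - field.values).max() < 1e-12

    def test_disabled_residuals_give_band_limited_output(self, unit_bundle, rng):
        _, intensity, bmat = unit_bundle
        noisy = SphericalIntensity(
            intensity.values + 0.1 * rng.normal(size=intensity.values.shape),
            intensity.grid,
        )
        out = modulus_project(noisy, eigendecompose_b(bmat), residual_grid=False)
        resynth = sht_inverse(sht_forward(out))
        assert np.abs(out.values - resynth.values).max() < 1e-9

    def test_approximate_idempotence(self, unit_bundle):
        _, intensity, bmat = unit_bundle
        pm = ModulusConstraint.from_b(bmat)
        once = pm(intensity)
        twice = pm(once)
        assert np.abs(twice.values - once.values).max() < 1e-6


class TestSupport:
    def test_single_peak_width_one(self):
        grid = SphericalGrid(8, 16, 2.0)
        peaks = BraggPeakList([[1, 0, 0]], [[0.9, 0.7, 0.4]], [1.0], 2.0)
        mask = build_support_mask(peaks, grid, 1, rotation=None)
        assert mask.values.sum() == 1

    def test_interior_peak_width_five(self):
        grid = SphericalGrid(16, 32, 2.0)
        peaks = BraggPeakList([[1, 0, 0]], [[0.9, 0.7, 0.4]], [1.0], 2.0)
        mask = build_support_mask(peaks, grid, 5, rotation=None)
        assert mask.values.sum() == 125
        assert mask.overlap_pairs == 0

    def test_even_width_rejected(self, bundle):
        with pytest.raises(ValueError, match="odd"):
            build_support_mask(bundle.peaks, bundle.grid, 4)

    def test_silver_nitrate_collision_regime(self, cells):
        """At coarse radial sampling the dense triclinic lattice produces
        overlapping support blocks (the sampling-collision regime)."""
        from braggfxs.lattice import enumerate_hkl

        peaks = enumerate_hkl(cells["silver_nitrate"], 6.0)
        grid = SphericalGrid(32, 32, 6.0)
        mask = build_support_mask(peaks, grid, 5)
        assert mask.overlap_pairs > 0

    def test_projection_clamps_and_masks(self, bundle, rng):
        field = SphericalIntensity(rng.normal(size=bundle.grid.shape), bundle.grid)
        out = support_project(field, bundle.mask)
        oracle = np.maximum(field.values, 0) * bundle.mask.values
        assert np.array_equal(out.values, oracle)

    def test_all_negative_input_zeroed(self, bundle):
        field = SphericalIntensity(-np.ones(bundle.grid.shape), bundle.grid)
        assert not support_project(field, bundle.mask).values.any()

    def test_exact_idempotence(self, bundle, rng):
        field = SphericalIntensity(rng.normal(size=bundle.grid.shape), bundle.grid)
        once = support_project(field, bundle.mask)
        twice = support_project(once, bundle.mask)
        assert np.array_equal(once.values, twice.values)


class TestAlternatingFixedPoint:
    def test_truth_is_a_joint_fixed_point(self, unit_bundle):
        """Alternating P_m/P_s on the true intensity keeps the R factor
        against the true peak intensities below 1e-3."""
        raw, intensity, bmat = unit_bundle
        pm = ModulusConstraint.from_b(bmat)
        state = intensity
        scale = np.abs(raw.intensity.values).max()
        for _ in range(2):
            state = support_project(pm(state), raw.mask)
            ex = extract_peak_intensities(
                state, raw.peaks, raw.support_width,
                rotation=raw.rotation, mode="integrate",
            )
            assert r_factor(ex * scale, raw.peaks.intensity) < 1e-3
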