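"""Projection operators: the modulus constraint P_m and support constraint P_s.

P_m makes the iterate's spherical-harmonic coefficients consistent with the
measured harmonic order matrices B(q1,q2,l): per degree, B is eigendecomposed,
the coefficients are expanded on the eigenvector basis (κ expansion), each
eigencomponent's m-vector is rescaled to length √λ, and the result is
synthesised back to the grid.  Both lossy steps — the band limit of the
spherical-harmonic transform and the finite κ basis — retain their residuals
and add them back, so content the constraint cannot see passes through
unchanged.

P_s zeroes intensity outside small blocks centred on the known Bragg-peak
voxels and clamps negative values to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import DEFAULT_ORIENTATION, peak_voxels
from .harmonics import (
    HarmonicCoefficients,
    HarmonicOrderMatrices,
    SphericalGrid,
    SphericalIntensity,
    sht_forward,
    sht_inverse,
)

__all__ = [
    "EigenBasis",
    "KappaCoefficients",
    "SupportMask",
    "eigendecompose_b",
    "kappa_expand",
    "kappa_inverse",
    "scale_kappa",
    "modulus_project",
    "ModulusConstraint",
    "build_support_mask",
    "support_project",
    "SupportConstraint",
]


@dataclass
class EigenBasis:
    """Per-degree spectral factors of B: eigvecs (n_l, n_q, n) columns,
    eigvals (n_l, n) descending and clamped ≥ 0."""

    eigvecs: np.ndarray
    eigvals: np.ndarray

    @property
    def n_l(self) -> int:
        return self.eigvecs.shape[0]

    @property
    def n_q(self) -> int:
        return self.eigvecs.shape[1]


@dataclass
class KappaCoefficients:
    """κ-expansion coefficients K_{lm,n}: array (n_l, 2n_l−1, n_modes)."""

    values: np.ndarray


def eigendecompose_b(b: HarmonicOrderMatrices, *, sym_tol: float = 1e-8) -> EigenBasis:
    """Per-degree symmetric eigendecomposition of B with a deterministic
    sign convention (largest-magnitude component of each eigenvector made
    positive) and negative eigenvalues clamped to zero."""
    vals = b.values
    n_q, _, n_l = vals.shape
    scale = max(np.abs(vals).max(), 1.0)
    asym = np.abs(vals - vals.transpose(1, 0, 2)).max()
    if asym > sym_tol * scale:
        raise ValueError(f"B not symmetric in (q1,q2): asymmetry {asym:.3g}")
    eigvecs = np.empty((n_l, n_q, n_q))
    eigvals = np.empty((n_l, n_q))
    for l in range(n_l):
        w, u = np.linalg.eigh(0.5 * (vals[:, :, l] + vals[:, :, l].T))
        order = np.argsort(w)[::-1]
        w, u = w[order], u[:, order]
        idx = np.argmax(np.abs(u), axis=0)
        signs = np.sign(u[idx, np.arange(n_q)])
        signs[signs == 0] = 1.0
        eigvecs[l] = u * signs[None, :]
        eigvals[l] = np.clip(w, 0.0, None)
    return EigenBasis(eigvecs, eigvals)


def kappa_expand(coeffs: HarmonicCoefficients, basis: EigenBasis) -> KappaCoefficients:
    """K_{lm,n} = Σ_q I_lm(q)·u_{l,n}(q)."""
    if coeffs.values.shape[0] != basis.n_q:
        raise ValueError("coefficient/basis q-bin mismatch")
    return KappaCoefficients(np.einsum("qlm,lqn->lmn", coeffs.values, basis.eigvecs))


def kappa_inverse(
    kappa: KappaCoefficients, basis: EigenBasis, grid: SphericalGrid
) -> HarmonicCoefficients:
    """I_lm(q) = Σ_n K_{lm,n}·u_{l,n}(q); orthogonal projection onto the
    eigenvector span when composed with :func:`kappa_expand`."""
    vals = np.einsum("lmn,lqn->qlm", kappa.values, basis.eigvecs)
    return HarmonicCoefficients(vals, grid)


def scale_kappa(kappa: KappaCoefficients, basis: EigenBasis) -> KappaCoefficients:
    """Rescale each eigencomponent's m-vector to length √λ_{l,n}.

    K'_{lm,n} = √λ_{l,n} · K_{lm,n} / (Σ_m K_{lm,n}²)^{1/2}; a vanishing norm
    or eigenvalue yields zero rather than NaN.  For coefficients whose own
    harmonic order matrix produced the basis, ‖K_{l·,n}‖² = λ_{l,n} and the
    rescaling is the identity.
    """
    k = kappa.values
    norms = np.sqrt((k ** 2).sum(axis=1, keepdims=True))  # (n_l, 1, n)
    lam = np.sqrt(basis.eigvals)[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(norms > 0, lam * k / norms, 0.0)
    return KappaCoefficients(out)


def modulus_project(
    intensity: SphericalIntensity,
    basis: EigenBasis,
    l_cut: int | None = None,
    *,
    residual_grid: bool = True,
    residual_kappa: bool = True,
) -> SphericalIntensity:
    """Apply the full modulus-constraint pipeline to an intensity iterate.

    Forward SHT → (grid residual retained) → κ expansion → (κ residual
    retained) → eigenvalue scaling → κ inverse + κ residual → inverse SHT +
    grid residual.  With ``residual_grid=False`` the output is exactly
    band-limited; with full-rank bases the κ residual is identically zero.
    """
    grid = intensity.grid
    if basis.n_q != grid.n_q:
        raise ValueError("basis/grid q-bin mismatch")
    coeffs = sht_forward(intensity)
    if residual_grid:
        lowpass = sht_inverse(coeffs)
        grid_residual = intensity.values - lowpass.values
    kappa = kappa_expand(coeffs, basis)
    if residual_kappa:
        filtered = kappa_inverse(kappa, basis, grid)
        coeff_residual = coeffs.values - filtered.values
    scaled = scale_kappa(kappa, basis)
    if l_cut is not None:
        scaled.values[l_cut:] = 0.0
    new_coeffs = kappa_inverse(scaled, basis, grid)
    if residual_kappa:
        new_coeffs = HarmonicCoefficients(new_coeffs.values + coeff_residual, grid)
    out = sht_inverse(new_coeffs)
    if residual_grid:
        out = SphericalIntensity(out.values + grid_residual, grid)
    return out


@dataclass
class ModulusConstraint:
    """Callable P_m bound to an eigenbasis and residual switches."""

    basis: EigenBasis
    l_cut: int | None = None
    residual_grid: bool = True
    residual_kappa: bool = True

    def __call__(self, intensity: SphericalIntensity) -> SphericalIntensity:
        return modulus_project(
            intensity,
            self.basis,
            self.l_cut,
            residual_grid=self.residual_grid,
            residual_kappa=self.residual_kappa,
        )

    @classmethod
    def from_b(cls, b: HarmonicOrderMatrices, l_cut: int | None = None, **kw):
        from .harmonics import truncate_b

        if l_cut is not None:
            b = truncate_b(b, l_cut)
        return cls(eigendecompose_b(b), **kw)


@dataclass
class SupportMask:
    """Binary mask of peak-centred blocks plus overlap diagnostics."""

    values: np.ndarray
    width: int
    n_peaks: int = 0
    overlap_pairs: int = 0
    n_clamped: int = 0
    peak_voxel_index: np.ndarray = field(default_factory=lambda: np.empty((0, 3), int))

    @property
    def fraction_set(self) -> float:
        return float(self.values.mean())


def build_support_mask(
    peaks,
    grid: SphericalGrid,
    width: int = 5,
    *,
    rotation=DEFAULT_ORIENTATION,
) -> SupportMask:
    """Binary mask setting a width³ index-space block around every peak voxel.

    Blocks are clamped at the radial and θ edges and wrap in φ.  The overlap
    count is the number of peak pairs whose blocks share at least one voxel
    (the sampling-collision regime): centres closer than ``width`` on every
    index axis.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be an odd positive integer")
    iq, it, ip, clamped = peak_voxels(peaks.q_vec, grid, rotation)
    h = width // 2
    mask = np.zeros(grid.shape, dtype=np.uint8)
    n_phi = grid.n_phi
    for a, b, c in zip(iq, it, ip):
        qs = slice(max(a - h, 0), min(a + h + 1, grid.n_q))
        ts = slice(max(b - h, 0), min(b + h + 1, grid.n_theta))
        ps = (np.arange(c - h, c + h + 1)) % n_phi
        mask[qs, ts, ps[None, None, :]] = 1
    dq_ = np.abs(iq[:, None] - iq[None, :])
    dt_ = np.abs(it[:, None] - it[None, :])
    dp_ = np.abs(ip[:, None] - ip[None, :])
    dp_ = np.minimum(dp_, n_phi - dp_)
    overlap = (dq_ < width) & (dt_ < width) & (dp_ < width)
    n_overlap = int((np.triu(overlap, 1)).sum())
    return SupportMask(
        mask,
        width,
        n_peaks=len(iq),
        overlap_pairs=n_overlap,
        n_clamped=int(clamped.sum()),
        peak_voxel_index=np.stack([iq, it, ip], axis=1),
    )


def support_project(intensity: SphericalIntensity, mask: SupportMask) -> SphericalIntensity:
    """P_s: elementwise max(I, 0)·M; exactly idempotent."""
    if intensity.values.shape != mask.values.shape:
        raise ValueError("intensity/mask shape mismatch")
    return SphericalIntensity(
        np.maximum(intensity.values, 0.0) * mask.values, intensity.grid
    )


@dataclass
class SupportConstraint:
    """Callable P_s bound to a mask."""

    mask: SupportMask

    def __call__(self, intensity: SphericalIntensity) -> SphericalIntensity:
        return support_project(intensity, self.mask)
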