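"""Spherical-harmonic machinery on the Driscoll–Healy equiangular grid.

The reciprocal-space intensity iterate I(q, θ, φ) lives on shells sampled at
q_j = (j+½)·q_max/n_q with an equiangular angular layout θ_j = πj/n_θ,
φ_k = 2πk/n_φ and n_φ = 2n_θ.  With the Driscoll–Healy quadrature weights the
forward/inverse transforms are exact inverses for fields band-limited below
n_l = n_θ/2.

The basis is the real orthonormal spherical harmonics (no Condon–Shortley
phase): Ȳ_lm = Λ_l|m|(θ)·{√2·cos mφ, 1, √2·sin|m|φ}/normalisation with
∫ Ȳ_lm² dΩ = 1.  The harmonic order matrix B(q1,q2,l) = Σ_m I_lm(q1)·I_lm(q2)
links coefficients to the correlation volume through the Legendre matrix F
(column l = P_l on the η grid): C ≈ F·B per (q1,q2), inverted with the
Moore–Penrose pseudo-inverse.  A raw pair-product histogram additionally
carries the analytic factor 2π·Δη (Legendre addition theorem plus δ-binning),
removed when ``from_histogram=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import eval_legendre, gammaln, lpmv

__all__ = [
    "SphericalGrid",
    "SphericalIntensity",
    "HarmonicCoefficients",
    "HarmonicOrderMatrices",
    "legendre_matrix",
    "sht_forward",
    "sht_inverse",
    "b_from_coeffs",
    "b_from_correlation",
    "truncate_b",
    "HISTOGRAM_B_FACTOR",
]


def driscoll_healy_weights(n_theta: int) -> np.ndarray:
    """Quadrature weights for θ_j = πj/n_θ with Σ w_j P_l(cosθ_j) = 2δ_l0, l < n_θ."""
    j = np.arange(n_theta)
    theta = np.pi * j / n_theta
    k = np.arange(n_theta // 2)
    series = np.sin((2 * k[None, :] + 1) * theta[:, None]) / (2 * k[None, :] + 1)
    w = np.sin(theta) * series.sum(axis=1)
    return 2.0 * w / w.sum()


@dataclass(frozen=True)
class SphericalGrid:
    """Sampling geometry shared by intensity volumes, masks and coefficients."""

    n_q: int
    n_theta: int
    q_max: float

    def __post_init__(self) -> None:
        if self.n_q < 1 or self.n_theta < 2 or self.n_theta % 2:
            raise ValueError("need n_q ≥ 1 and even n_theta ≥ 2")
        if self.q_max <= 0:
            raise ValueError("q_max must be positive")

    @property
    def n_phi(self) -> int:
        return 2 * self.n_theta

    @property
    def n_l(self) -> int:
        return self.n_theta // 2

    @property
    def dq(self) -> float:
        return self.q_max / self.n_q

    @property
    def q_centers(self) -> np.ndarray:
        return (np.arange(self.n_q) + 0.5) * self.dq

    @property
    def thetas(self) -> np.ndarray:
        return np.pi * np.arange(self.n_theta) / self.n_theta

    @property
    def phis(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_phi) / self.n_phi

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_q, self.n_theta, self.n_phi)


@dataclass
class SphericalIntensity:
    """I(q, θ, φ) on a Driscoll–Healy grid."""

    values: np.ndarray
    grid: SphericalGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    def copy(self) -> "SphericalIntensity":
        return SphericalIntensity(self.values.copy(), self.grid)


@dataclass
class HarmonicCoefficients:
    """Real coefficients I_lm(q): array (n_q, n_l, 2n_l−1), m index = m + n_l − 1."""

    values: np.ndarray
    grid: SphericalGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        n_l = self.grid.n_l
        if self.values.shape != (self.grid.n_q, n_l, 2 * n_l - 1):
            raise ValueError("coefficient array shape mismatch")

    @property
    def n_l(self) -> int:
        return self.grid.n_l

    def copy(self) -> "HarmonicCoefficients":
        return HarmonicCoefficients(self.values.copy(), self.grid)


@dataclass
class HarmonicOrderMatrices:
    """B(q1, q2, l) stack, symmetric in (q1, q2) for each degree l."""

    values: np.ndarray
    q_max: float
    l_max_used: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 3 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("B must be n_q × n_q × n_l")
        if self.l_max_used is None:
            self.l_max_used = self.values.shape[2] - 1

    @property
    def n_q(self) -> int:
        return self.values.shape[0]

    @property
    def n_l(self) -> int:
        return self.values.shape[2]


class _SHTCache:
    """Per-(n_theta) tables: normalised Legendre functions, trig bases, weights."""

    _store: dict[int, "_SHTCache"] = {}

    def __init__(self, n_theta: int):
        n_l = n_theta // 2
        thetas = np.pi * np.arange(n_theta) / n_theta
        x = np.cos(thetas)
        # Λ_lm(θ) = sqrt((2l+1)/2 · (l−m)!/(l+m)!) · P_l^m(cosθ), CS phase removed
        lam = np.zeros((n_theta, n_l, n_l))
        for l in range(n_l):
            for m in range(l + 1):
                norm = np.exp(
                    0.5 * (np.log(2 * l + 1.0) - np.log(2.0)
                           + gammaln(l - m + 1) - gammaln(l + m + 1))
                )
                lam[:, l, m] = ((-1.0) ** m) * norm * lpmv(m, l, x)
        self.lam = lam
        self.weights = driscoll_healy_weights(n_theta)
        n_phi = 2 * n_theta
        phis = 2.0 * np.pi * np.arange(n_phi) / n_phi
        m = np.arange(n_l)
        self.cos = np.cos(m[None, :] * phis[:, None])  # (n_phi, n_l)
        self.sin = np.sin(m[None, :] * phis[:, None])
        self.n_theta = n_theta
        self.n_l = n_l
        self.n_phi = n_phi

    @classmethod
    def get(cls, n_theta: int) -> "_SHTCache":
        if n_theta not in cls._store:
            cls._store[n_theta] = cls(n_theta)
        return cls._store[n_theta]


def sht_forward(intensity: SphericalIntensity) -> HarmonicCoefficients:
    """Forward transform: I_lm(q) = ∮ I(q,θ,φ) Ȳ_lm(θ,φ) dΩ via DH quadrature.

    Exact for fields band-limited below n_l = n_θ/2 (the quadrature is exact
    for the degree < n_θ products arising there).
    """
    grid = intensity.grid
    c = _SHTCache.get(grid.n_theta)
    f = intensity.values  # (n_q, n_theta, n_phi)
    dphi = 2.0 * np.pi / grid.n_phi
    # azimuthal projections: a_m = ∫ f cos(mφ) dφ, b_m = ∫ f sin(mφ) dφ
    a = np.einsum("qtp,pm->qtm", f, c.cos) * dphi
    b = np.einsum("qtp,pm->qtm", f, c.sin) * dphi
    ga = np.einsum("qtm,t,tlm->qlm", a, c.weights, c.lam)
    gb = np.einsum("qtm,t,tlm->qlm", b, c.weights, c.lam)
    n_l = grid.n_l
    out = np.zeros((grid.n_q, n_l, 2 * n_l - 1))
    # m = 0: Φ = 1/√(2π); m > 0: cos·(1/√π); m < 0: sin·(1/√π)
    out[:, :, n_l - 1] = ga[:, :, 0] / np.sqrt(2.0 * np.pi)
    for m in range(1, n_l):
        out[:, :, n_l - 1 + m] = ga[:, :, m] / np.sqrt(np.pi)
        out[:, :, n_l - 1 - m] = gb[:, :, m] / np.sqrt(np.pi)
    # zero entries with |m| > l (Λ is zero there already, but keep exact zeros)
    for l in range(n_l):
        out[:, l, : n_l - 1 - l] = 0.0
        out[:, l, n_l + l:] = 0.0
    return HarmonicCoefficients(out, grid)


def sht_inverse(coeffs: HarmonicCoefficients, n_theta: int | None = None) -> SphericalIntensity:
    """Inverse transform: I(q,θ,φ) = Σ_lm I_lm(q) Ȳ_lm(θ,φ)."""
    grid = coeffs.grid
    if n_theta is not None and n_theta != grid.n_theta:
        grid = SphericalGrid(grid.n_q, n_theta, grid.q_max)
        if grid.n_l < coeffs.n_l:
            raise ValueError("target grid cannot hold the coefficient band limit")
    c = _SHTCache.get(grid.n_theta)
    n_l = coeffs.n_l
    v = coeffs.values
    # split by azimuthal parity
    am = np.zeros((v.shape[0], n_l, n_l))
    bm = np.zeros_like(am)
    am[:, :, 0] = v[:, :, n_l - 1]
    for m in range(1, n_l):
        am[:, :, m] = v[:, :, n_l - 1 + m]
        bm[:, :, m] = v[:, :, n_l - 1 - m]
    lam = c.lam[:, :n_l, :n_l]
    ga = np.einsum("qlm,tlm->qtm", am, lam)
    gb = np.einsum("qlm,tlm->qtm", bm, lam)
    phi_cos = c.cos[:, :n_l].copy()
    phi_sin = c.sin[:, :n_l].copy()
    phi_cos[:, 0] /= np.sqrt(2.0)
    out = (np.einsum("qtm,pm->qtp", ga, phi_cos)
           + np.einsum("qtm,pm->qtp", gb, phi_sin)) / np.sqrt(np.pi)
    return SphericalIntensity(out, grid)


def legendre_matrix(eta_grid: np.ndarray, n_l: int) -> np.ndarray:
    """F matrix: F[k, l] = P_l(η_k).  Column 0 is all ones."""
    eta_grid = np.asarray(eta_grid, float)
    l = np.arange(n_l)
    return eval_legendre(l[None, :], eta_grid[:, None])


def b_from_coeffs(coeffs: HarmonicCoefficients) -> HarmonicOrderMatrices:
    """B(q1,q2,l) = Σ_m I_lm(q1)·I_lm(q2); symmetric and PSD per degree."""
    v = coeffs.values
    b = np.einsum("alm,blm->abl", v, v)
    return HarmonicOrderMatrices(b, coeffs.grid.q_max)


# analytic histogram→B factor per unit Δη: C_hist ≈ 2π·Δη · Σ_l B_l P_l(η)
HISTOGRAM_B_FACTOR = 2.0 * np.pi


def b_from_correlation(
    volume,
    n_l: int,
    *,
    F: np.ndarray | None = None,
    rcond: float = 1e-10,
    from_histogram: bool = False,
) -> HarmonicOrderMatrices:
    """Extract B(q1,q2,l) from an η-parametrised correlation volume.

    Solves C(q1,q2,·) = F·B(q1,q2,·) per radial pair in the least-squares
    sense with the Moore–Penrose pseudo-inverse of F (n_η × n_l, n_η ≥ n_l).
    With ``from_histogram=True`` the raw pair-product histogram normalisation
    2π·Δη is removed so the result is on the Σ_m I_lm(q1)I_lm(q2) scale.
    """
    if volume.angular_coordinate != "eta":
        raise ValueError("correlation must be η-parametrised")
    n_eta = volume.n_angle
    if n_eta < n_l:
        raise ValueError("underdetermined: n_eta < n_l")
    if F is None:
        F = legendre_matrix(volume.angle_centers, n_l)
    Finv = np.linalg.pinv(F, rcond=rcond)
    b = np.einsum("lk,abk->abl", Finv, volume.values)
    if from_histogram:
        d_eta = 2.0 / n_eta
        b /= HISTOGRAM_B_FACTOR * d_eta
    return HarmonicOrderMatrices(b, volume.q_max)


def truncate_b(b: HarmonicOrderMatrices, l_cut: int) -> HarmonicOrderMatrices:
    """Zero all degrees l ≥ l_cut, leaving lower degrees untouched."""
    if l_cut < 0 or l_cut > b.n_l:
        raise ValueError("l_cut outside the allocated degree range")
    out = b.values.copy()
    out[:, :, l_cut:] = 0.0
    return HarmonicOrderMatrices(out, b.q_max, l_max_used=max(l_cut - 1, 0))
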