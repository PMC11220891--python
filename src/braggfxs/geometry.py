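"""Mapping between Bragg-peak vectors and spherical-grid voxels.

Radial samples sit at bin centres q_j = (j+½)·dq, so floor binning assigns a
peak to its nearest radial sample; θ and φ use nearest equiangular sample
with φ wraparound.  A fixed generic rotation can be applied to all q-vectors
before mapping: angular correlations are rotation invariant, and a generic
orientation keeps reflections off the θ = 0 pole row whose Driscoll–Healy
quadrature weight vanishes (axial (0,0,l) reflections lie exactly on +z in
the standard crystallographic frame).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .harmonics import SphericalGrid, SphericalIntensity, _SHTCache

__all__ = [
    "DEFAULT_ORIENTATION",
    "peak_voxels",
    "solid_angle_weights",
    "deposit_peaks",
]

# generic orientation (intrinsic zyx Euler angles, radians); any rotation that
# leaves no reciprocal-lattice axis along z works
DEFAULT_ORIENTATION = Rotation.from_euler("zyx", [0.37, 1.14, 2.53])


def peak_voxels(
    q_vec: np.ndarray,
    grid: SphericalGrid,
    rotation: Rotation | None = DEFAULT_ORIENTATION,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Voxel indices (iq, iθ, iφ) for each q-vector plus a clamped-flag array.

    iθ is kept off the zero-weight pole row (clamped into [1, n_θ−1]); the
    flag marks peaks whose radial index needed clamping at the grid edge.
    """
    q_vec = np.asarray(q_vec, float).reshape(-1, 3)
    if rotation is not None:
        q_vec = rotation.apply(q_vec)
    qmag = np.linalg.norm(q_vec, axis=1)
    theta = np.arccos(np.clip(q_vec[:, 2] / np.where(qmag > 0, qmag, 1.0), -1, 1))
    phi = np.mod(np.arctan2(q_vec[:, 1], q_vec[:, 0]), 2.0 * np.pi)
    iq_raw = np.floor(qmag / grid.dq).astype(int)
    clamped = (iq_raw < 0) | (iq_raw >= grid.n_q)
    iq = np.clip(iq_raw, 0, grid.n_q - 1)
    it = np.rint(theta / (np.pi / grid.n_theta)).astype(int)
    it = np.clip(it, 1, grid.n_theta - 1)
    ip = np.rint(phi / (2.0 * np.pi / grid.n_phi)).astype(int) % grid.n_phi
    return iq, it, ip, clamped


def solid_angle_weights(grid: SphericalGrid) -> np.ndarray:
    """Per-voxel solid-angle quadrature weights W[θ] (shared across φ columns).

    Σ_{θ,φ} W[θ]·f(θ,φ) approximates the surface integral ∮ f dΩ and is exact
    for band-limited f.
    """
    cache = _SHTCache.get(grid.n_theta)
    return cache.weights * (2.0 * np.pi / grid.n_phi)


def deposit_peaks(
    peaks,
    grid: SphericalGrid,
    rotation: Rotation | None = DEFAULT_ORIENTATION,
    *,
    mode: str = "density",
) -> SphericalIntensity:
    """Place peak intensities on the grid (one voxel per peak).

    mode "density" divides each intensity by its voxel's solid-angle weight so
    that the deposited function integrates (per shell) to the peak intensity —
    the convention under which the grid's harmonic coefficients equal the
    phasor sums Σ_i I_i Ȳ_lm(Ω_i) that the correlation volume encodes.  mode
    "value" stores the raw intensity in the voxel.
    """
    if mode not in ("density", "value"):
        raise ValueError("mode must be 'density' or 'value'")
    iq, it, ip, _ = peak_voxels(peaks.q_vec, grid, rotation)
    vals = np.zeros(grid.shape)
    w = solid_angle_weights(grid)
    for i, (a, b, c) in enumerate(zip(iq, it, ip)):
        v = peaks.intensity[i]
        vals[a, b, c] += v / w[b] if mode == "density" else v
    return SphericalIntensity(vals, grid)
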