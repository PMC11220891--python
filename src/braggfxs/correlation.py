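"""Angular intensity correlation functions of fluctuation X-ray scattering.

Two correlators are provided: the 3D "ground truth" correlator over a list of
3D Bragg peaks (double sum over all ordered pairs, binned in
(q1, q2, η = cos∠(q1,q2))), and the per-pattern 2D correlator over detector
peak lists binned in (q1, q2, ψ), averaged over patterns.  Both realise the
Dirac delta of the pair sums as nearest-bin histogram assignment with uniform
bins: q over [0, q_max], η over [−1, 1], ψ over [0, π].

The ψ↔η conversion applies the Ewald-sphere re-parametrisation
θ(q) = π/2 + arcsin(q/2k) together with the |q1||q2| curvature factor and the
sin-based Jacobian relating the two angular densities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "CorrelationVolume",
    "PeakList2D",
    "correlate_3d",
    "correlate_2d",
    "convert_psi_eta",
    "ewald_theta",
    "psi_to_eta_value",
    "save_volume",
    "load_volume",
]


@dataclass
class CorrelationVolume:
    """C(q1, q2, angle) on a uniform grid.

    ``angular_coordinate`` is "eta" (grid spans [−1, 1]) or "psi" (grid spans
    [0, π]).  Values carry arbitrary (intensity²) units.
    """

    values: np.ndarray
    q_max: float
    angular_coordinate: str = "eta"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 3 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("values must be an n_q × n_q × n_angle array")
        if self.angular_coordinate not in ("eta", "psi"):
            raise ValueError("angular_coordinate must be 'eta' or 'psi'")

    @property
    def n_q(self) -> int:
        return self.values.shape[0]

    @property
    def n_angle(self) -> int:
        return self.values.shape[2]

    @property
    def q_centers(self) -> np.ndarray:
        dq = self.q_max / self.n_q
        return (np.arange(self.n_q) + 0.5) * dq

    @property
    def angle_centers(self) -> np.ndarray:
        n = self.n_angle
        if self.angular_coordinate == "eta":
            return -1.0 + (np.arange(n) + 0.5) * (2.0 / n)
        return (np.arange(n) + 0.5) * (np.pi / n)


@dataclass
class PeakList2D:
    """Detector peaks of a single pattern: (q magnitude, azimuth φ, intensity)."""

    q_mag: np.ndarray
    phi: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.q_mag = np.asarray(self.q_mag, float).reshape(-1)
        self.phi = np.mod(np.asarray(self.phi, float).reshape(-1), 2.0 * np.pi)
        self.intensity = np.asarray(self.intensity, float).reshape(-1)
        if np.any(self.q_mag < 0):
            raise ValueError("q magnitudes must be non-negative")


def _q_bin(qmag: np.ndarray, q_max: float, n_q: int) -> np.ndarray:
    """Uniform floor binning over [0, q_max]; top edge clamped into last bin."""
    idx = np.floor(qmag / q_max * n_q).astype(int)
    return np.clip(idx, 0, n_q - 1)


def _angle_bin(x: np.ndarray, lo: float, hi: float, n: int) -> np.ndarray:
    idx = np.floor((x - lo) / (hi - lo) * n).astype(int)
    return np.clip(idx, 0, n - 1)


def correlate_3d(
    peaks,
    n_q: int,
    n_eta: int,
    q_max: float,
    *,
    include_self: bool = True,
    chunk: int = 1024,
) -> CorrelationVolume:
    """3D correlation: ordered double sum of I_i·I_j over all peak pairs.

    Each ordered pair accumulates I_i·I_j into
    (bin(q_i), bin(q_j), bin(η_ij)) with η_ij = q̂_i·q̂_j clamped to [−1, 1].
    Self-pairs (i = j, η = 1) are included by default so that the volume total
    equals (Σ_i I_i)².
    """
    if n_q < 2 or n_eta < 2:
        raise ValueError("n_q and n_eta must each be at least 2")
    if len(peaks) == 0:
        raise ValueError("peak list is empty")
    qmag = peaks.q_mag
    if np.any(qmag > q_max * (1 + 1e-12)):
        raise ValueError("peak with q_mag > q_max")
    unit = peaks.q_vec / qmag[:, None]
    inten = peaks.intensity
    qbin = _q_bin(qmag, q_max, n_q)
    out = np.zeros((n_q, n_q, n_eta))
    n = len(inten)
    flat = out.reshape(-1)
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        eta = np.clip(unit[sl] @ unit.T, -1.0, 1.0)
        w = inten[sl, None] * inten[None, :]
        ebin = _angle_bin(eta, -1.0, 1.0, n_eta)
        lin = (qbin[sl, None] * n_q + qbin[None, :]) * n_eta + ebin
        if not include_self:
            rows = np.arange(sl.start, sl.stop)
            w = w.copy()
            w[rows - sl.start, rows] = 0.0
        np.add.at(flat, lin.ravel(), w.ravel())
    return CorrelationVolume(out, q_max, "eta")


def correlate_2d(
    patterns: Iterable[PeakList2D],
    n_q: int,
    n_psi: int,
    q_max: float,
    *,
    include_self: bool = True,
) -> CorrelationVolume:
    """2D correlation averaged over patterns; ψ = |φ_i − φ_j| wrapped to [0, π]."""
    if n_q < 2 or n_psi < 2:
        raise ValueError("n_q and n_psi must each be at least 2")
    patterns = list(patterns)
    if not patterns:
        raise ValueError("need at least one pattern")
    out = np.zeros((n_q, n_q, n_psi))
    flat = out.reshape(-1)
    for pat in patterns:
        if np.any(pat.q_mag > q_max * (1 + 1e-12)):
            raise ValueError("peak with q_mag > q_max")
        psi = np.abs(pat.phi[:, None] - pat.phi[None, :]) % (2.0 * np.pi)
        psi = np.minimum(psi, 2.0 * np.pi - psi)
        w = pat.intensity[:, None] * pat.intensity[None, :]
        if not include_self:
            np.fill_diagonal(w, 0.0)
        qbin = _q_bin(pat.q_mag, q_max, n_q)
        pbin = _angle_bin(psi, 0.0, np.pi, n_psi)
        lin = (qbin[:, None] * n_q + qbin[None, :]) * n_psi + pbin
        np.add.at(flat, lin.ravel(), w.ravel())
    out /= len(patterns)
    return CorrelationVolume(out, q_max, "psi")


def ewald_theta(q: np.ndarray | float, k: float) -> np.ndarray | float:
    """Polar angle θ(q) of the Ewald sphere at wavenumber k: π/2 + arcsin(q/2k)."""
    q = np.asarray(q, float)
    if np.any(q > 2 * k):
        raise ValueError("q exceeds the Ewald diameter 2k")
    return np.pi / 2.0 + np.arcsin(q / (2.0 * k))


def psi_to_eta_value(q1: float, q2: float, psi: float, k: float | None) -> float:
    """η = cos∠ between two Ewald-sphere scattering vectors at azimuth split ψ.

    η = cosθ(q1)cosθ(q2) + sinθ(q1)sinθ(q2)cosψ; the flat-Ewald limit
    (k = None or ∞) reduces to η = cos ψ.
    """
    if k is None or np.isinf(k):
        return float(np.cos(psi))
    t1, t2 = ewald_theta(q1, k), ewald_theta(q2, k)
    return float(np.cos(t1) * np.cos(t2) + np.sin(t1) * np.sin(t2) * np.cos(psi))


def convert_psi_eta(
    volume: CorrelationVolume,
    k: float | None,
    direction: str = "psi_to_eta",
    *,
    n_out: int | None = None,
    apply_q_factor: bool = True,
) -> CorrelationVolume:
    """Re-parametrise a correlation volume between ψ and η sampling.

    The ψ-sampled (2D) and η-sampled (3D) functions are related by the
    |q1||q2| Ewald-curvature factor and the Jacobian
    |dη/dψ| = sinθ(q1)·sinθ(q2)·sinψ.  ``k`` is the beam wavenumber in Å⁻¹
    (None for the flat-Ewald limit, where η = cos ψ).  Requires k > q_max/2.
    Resampling uses a clamped cubic spline, so the round trip is exact only up
    to interpolation error on band-limited volumes.
    """
    if direction not in ("psi_to_eta", "eta_to_psi"):
        raise ValueError("direction must be 'psi_to_eta' or 'eta_to_psi'")
    if k is not None and k <= volume.q_max / 2.0:
        raise ValueError("geometry error: need wavenumber k > q_max/2")
    n_q = volume.n_q
    n_out = n_out or volume.n_angle
    q = volume.q_centers
    theta = ewald_theta(q, k) if k is not None else np.full(n_q, np.pi / 2.0)

    if direction == "psi_to_eta":
        if volume.angular_coordinate != "psi":
            raise ValueError("input volume is not ψ-parametrised")
        eta_out = -1.0 + (np.arange(n_out) + 0.5) * (2.0 / n_out)
        out = np.zeros((n_q, n_q, n_out))
        psi_in = volume.angle_centers
        for i in range(n_q):
            for j in range(n_q):
                c1, c2 = np.cos(theta[i]), np.cos(theta[j])
                s1, s2 = np.sin(theta[i]), np.sin(theta[j])
                # interpolate in ψ, where the volume is smooth; the η↔ψ map
                # has a square-root singularity at the η range edges
                spl = CubicSpline(psi_in, volume.values[i, j], extrapolate=False)
                u = (eta_out - c1 * c2) / (s1 * s2)
                inside = np.abs(u) <= 1.0
                psi_of_eta = np.arccos(np.clip(u, -1.0, 1.0))
                vals = np.where(inside, np.nan_to_num(spl(psi_of_eta), nan=0.0), 0.0)
                jac = s1 * s2 * np.sqrt(np.clip(1.0 - u * u, 0.0, None))
                factor = (q[i] * q[j]) if apply_q_factor else 1.0
                with np.errstate(divide="ignore", invalid="ignore"):
                    out[i, j] = factor * np.where(jac > 1e-12, vals / jac, 0.0)
        return CorrelationVolume(out, volume.q_max, "eta")

    if volume.angular_coordinate != "eta":
        raise ValueError("input volume is not η-parametrised")
    psi_out = (np.arange(n_out) + 0.5) * (np.pi / n_out)
    out = np.zeros((n_q, n_q, n_out))
    eta_in = volume.angle_centers
    for i in range(n_q):
        for j in range(n_q):
            c1, c2 = np.cos(theta[i]), np.cos(theta[j])
            s1, s2 = np.sin(theta[i]), np.sin(theta[j])
            # map the η grid to its ψ preimage and fit the bounded product
            # C_η·|dη/dψ| on that (non-uniform but smooth) axis
            u_in = (eta_in - c1 * c2) / (s1 * s2)
            ok = np.abs(u_in) <= 1.0
            psi_of_eta = np.arccos(np.clip(u_in, -1.0, 1.0))
            jac_in = s1 * s2 * np.sqrt(np.clip(1.0 - u_in * u_in, 0.0, None))
            x = psi_of_eta[ok][::-1]
            y = (volume.values[i, j] * jac_in)[ok][::-1]
            if len(x) < 4:
                continue
            spl = CubicSpline(x, y, extrapolate=False)
            vals = np.nan_to_num(spl(psi_out), nan=0.0)
            factor = (q[i] * q[j]) if apply_q_factor else 1.0
            out[i, j] = vals / factor
    return CorrelationVolume(out, volume.q_max, "psi")


def save_volume(path: str | Path, volume: CorrelationVolume) -> None:
    """Persist to a .npz container plus a JSON sidecar header."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), values=volume.values)
    meta = {
        "n_q": volume.n_q,
        "n_angle": volume.n_angle,
        "q_max": volume.q_max,
        "angular_coordinate": volume.angular_coordinate,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_volume(path: str | Path) -> CorrelationVolume:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    values = np.load(path.with_suffix(".npz"))["values"]
    return CorrelationVolume(values, meta["q_max"], meta["angular_coordinate"])
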