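"""Quality metrics: R factor, R_iso between runs, mean atomic displacement,
and per-peak intensity extraction from recovered volumes."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import DEFAULT_ORIENTATION, peak_voxels, solid_angle_weights
from .harmonics import SphericalIntensity

__all__ = [
    "extract_peak_intensities",
    "r_factor",
    "r_iso",
    "mean_atomic_displacement",
    "read_xyz",
    "write_xyz",
]


def extract_peak_intensities(
    intensity: SphericalIntensity,
    peaks,
    width: int = 5,
    *,
    rotation=DEFAULT_ORIENTATION,
    mode: str = "sum",
) -> "np.ndarray":
    """Per-peak accumulation of the iterate over each peak's support block.

    mode "sum" adds raw voxel values (a uniform field of 1 under an interior
    width-5 block gives 125).  mode "integrate" weights each voxel by its
    solid-angle quadrature weight, approximating the per-shell surface
    integral of the peak's intensity bump; the recovery pipeline uses this
    mode because the iterate represents intensity per unit solid angle.
    Returns the intensity array aligned with ``peaks``.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be an odd positive integer")
    if mode not in ("sum", "integrate"):
        raise ValueError("mode must be 'sum' or 'integrate'")
    grid = intensity.grid
    iq, it, ip, clamped = peak_voxels(peaks.q_vec, grid, rotation)
    h = width // 2
    w = solid_angle_weights(grid)
    out = np.empty(len(iq))
    for i, (a, b, c) in enumerate(zip(iq, it, ip)):
        qs = slice(max(a - h, 0), min(a + h + 1, grid.n_q))
        ts = slice(max(b - h, 0), min(b + h + 1, grid.n_theta))
        ps = np.arange(c - h, c + h + 1) % grid.n_phi
        block = intensity.values[qs, ts][:, :, ps]
        if mode == "integrate":
            block = block * w[ts][None, :, None]
        out[i] = block.sum()
    return out


def _amplitudes(intensity: np.ndarray) -> np.ndarray:
    return np.sqrt(np.clip(np.asarray(intensity, float), 0.0, None))


def r_factor(i_obs, i_calc) -> float:
    """Crystallographic R factor on structure-factor amplitudes.

    R = Σ_hkl | √I_obs − √I_calc | / Σ_hkl √I_obs over matched peak sets;
    0 for identical inputs, sensitive to a global scale mismatch.
    """
    i_obs = getattr(i_obs, "intensity", i_obs)
    i_calc = getattr(i_calc, "intensity", i_calc)
    fo, fc = _amplitudes(i_obs), _amplitudes(i_calc)
    if fo.shape != fc.shape:
        raise ValueError("peak sets differ in length")
    denom = fo.sum()
    if denom == 0:
        raise ZeroDivisionError("undefined R factor: zero observed amplitudes")
    return float(np.abs(fo - fc).sum() / denom)


def r_iso(run_i, run_j) -> float:
    """Discrepancy between two independent recoveries of the same peak set.

    R_iso = Σ|√I_i − √I_j| / (½ Σ(√I_i + √I_j)); symmetric in (i, j) and 0
    for identical runs.
    """
    i_i = getattr(run_i, "intensity", run_i)
    i_j = getattr(run_j, "intensity", run_j)
    fi, fj = _amplitudes(i_i), _amplitudes(i_j)
    if fi.shape != fj.shape:
        raise ValueError("peak sets differ in length")
    denom = 0.5 * (fi + fj).sum()
    if denom == 0:
        raise ZeroDivisionError("undefined R_iso: both runs are all zero")
    return float(np.abs(fi - fj).sum() / denom)


def mean_atomic_displacement(target: np.ndarray, probe: np.ndarray) -> float:
    """Mean Euclidean distance (Å) between matched atoms of two structures."""
    target = np.asarray(target, float).reshape(-1, 3)
    probe = np.asarray(probe, float).reshape(-1, 3)
    if target.shape != probe.shape:
        raise ValueError("coordinate sets differ in size")
    return float(np.linalg.norm(target - probe, axis=1).mean())


def read_xyz(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Simple XYZ-style text: optional count/comment header then 'El x y z'."""
    labels, coords = [], []
    lines = Path(path).read_text().splitlines()
    start = 0
    if lines and lines[0].strip().isdigit():
        start = 2
    for line in lines[start:]:
        toks = line.split()
        if len(toks) < 4:
            continue
        labels.append(toks[0])
        coords.append([float(t) for t in toks[1:4]])
    return labels, np.asarray(coords, float).reshape(-1, 3)


def write_xyz(path: str | Path, labels, coords, comment: str = "") -> None:
    coords = np.asarray(coords, float).reshape(-1, 3)
    with open(path, "w") as fh:
        fh.write(f"{len(coords)}\n{comment}\n")
        for lab, (x, y, z) in zip(labels, coords):
            fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")
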