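"""Synthetic test-data factory: toy crystals and self-consistent fixtures.

A fixture bundle carries a small unit cell, a random point-atom motif, its
|F|² Bragg intensities on the enumerated reciprocal lattice, the matching 3D
correlation volume, a harmonic-order-matrix stack, a support mask and the
ground-truth gridded intensity — all mutually consistent, so projector and
recovery tests can assert exact fixed points.

Toy grids default to n_q = 32, n_θ = 32 (n_φ = 64), n_η = 128 so that full
fixture suites run in seconds; production-scale sampling (n_q = 300,
n_η = 5760) is reserved for explicit scripts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constraints import SupportMask, build_support_mask
from .correlation import CorrelationVolume, correlate_3d
from .geometry import DEFAULT_ORIENTATION, deposit_peaks
from .harmonics import (
    HarmonicOrderMatrices,
    SphericalGrid,
    SphericalIntensity,
    b_from_coeffs,
    sht_forward,
)
from .lattice import AtomicModel, BraggPeakList, UnitCell, enumerate_hkl, structure_factor_intensities

__all__ = ["FixtureBundle", "make_toy_crystal", "published_test_cells", "TOY_CELLS"]

TOY_CELLS = {
    "cubic": UnitCell(5.5, 5.5, 5.5, 90.0, 90.0, 90.0),
    "triclinic": UnitCell(4.8, 5.6, 6.4, 96.0, 101.0, 88.0),
    "monoclinic": UnitCell(5.2, 6.0, 6.8, 90.0, 99.0, 90.0),
    "orthorhombic": UnitCell(5.0, 6.0, 7.0, 90.0, 90.0, 90.0),
}


@dataclass
class FixtureBundle:
    """Internally consistent synthetic crystal with all derived arrays."""

    cell: UnitCell
    model: AtomicModel
    peaks: BraggPeakList
    correlation: CorrelationVolume
    b: HarmonicOrderMatrices
    mask: SupportMask
    intensity: SphericalIntensity
    grid: SphericalGrid
    support_width: int
    rotation: object = DEFAULT_ORIENTATION


def make_toy_crystal(
    seed: int,
    n_atoms: int = 5,
    cell_kind: str = "triclinic",
    q_max: float = 3.2,
    *,
    n_q: int = 32,
    n_theta: int = 32,
    n_eta: int = 128,
    support_width: int = 3,
    rotation=DEFAULT_ORIENTATION,
    peak_cap: int = 200_000,
) -> FixtureBundle:
    """Deterministic toy crystal bundle (same seed → identical bundle).

    Atoms are uniform in the cell with scattering weights in [1, 2]; real
    weights make the |F|² intensities Friedel symmetric.  The ground-truth
    grid holds the peak intensities as per-voxel surface densities, so its
    harmonic coefficients equal the phasor sums the correlation encodes.
    """
    if n_atoms < 1:
        raise ValueError("need at least one atom")
    if cell_kind not in TOY_CELLS:
        raise ValueError(f"unknown cell kind {cell_kind!r}")
    cell = TOY_CELLS[cell_kind]
    rng = np.random.default_rng(seed)
    model = AtomicModel(
        rng.uniform(0.0, 1.0, size=(n_atoms, 3)),
        rng.uniform(1.0, 2.0, size=n_atoms),
    )
    peaks = enumerate_hkl(cell, q_max, count_cap=peak_cap)
    if len(peaks) < 10:
        raise ValueError("q_max too small: fewer than 10 reflections")
    peaks = structure_factor_intensities(model, peaks)
    correlation = correlate_3d(peaks, n_q, n_eta, q_max)
    grid = SphericalGrid(n_q, n_theta, q_max)
    intensity = deposit_peaks(peaks, grid, rotation, mode="density")
    b = b_from_coeffs(sht_forward(intensity))
    mask = build_support_mask(peaks, grid, support_width, rotation=rotation)
    return FixtureBundle(
        cell, model, peaks, correlation, b, mask, intensity, grid,
        support_width, rotation,
    )


def published_test_cells() -> dict[str, UnitCell]:
    """The three published test cells (triclinic silver nitrate with ligand,
    monoclinic aluminophosphate, orthorhombic dipeptide precursor)."""
    return {
        "silver_nitrate": UnitCell(5.187, 10.722, 12.636, 82.315, 78.712, 79.952),
        "aluminophosphate": UnitCell(7.8783, 10.46890, 16.0680, 90.0, 95.1470, 90.0),
        "dipeptide": UnitCell(9.9400, 14.9395, 17.876, 90.0, 90.0, 90.0),
    }
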