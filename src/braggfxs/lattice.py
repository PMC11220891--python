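"""Unit-cell geometry, reciprocal-lattice enumeration and toy structure factors.

The reciprocal basis follows the crystallographic 2π convention
(``a_i · a*_j = 2π δ_ij``), so scattering magnitudes relate to resolution by
``q = 2π/d``.  Real-space basis vectors are laid out in the standard frame:
**a** along x, **b** in the xy plane, **c** completing a right-handed set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "UnitCell",
    "BraggPeakList",
    "AtomicModel",
    "InvalidCellError",
    "EnumerationSizeError",
    "reciprocal_basis",
    "enumerate_hkl",
    "structure_factor_intensities",
    "resolution_to_qmax",
    "qmax_to_resolution",
    "read_reflections",
    "write_reflections",
    "read_cell_cif",
]


class InvalidCellError(ValueError):
    """Raised for degenerate or impossible unit-cell parameters."""


class EnumerationSizeError(RuntimeError):
    """Raised when a reflection enumeration would exceed the configured cap."""


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise InvalidCellError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise InvalidCellError("cell angles must lie in (0, 180) degrees")
        ca, cb, cg = np.cos(np.radians([self.alpha, self.beta, self.gamma]))
        # squared volume factor of the metric tensor; <= 0 means the three
        # angles cannot close a parallelepiped
        v2 = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if v2 <= 0.0:
            raise InvalidCellError("angle combination gives a degenerate cell")

    @property
    def direct_basis(self) -> np.ndarray:
        """3x3 matrix with rows a, b, c in Cartesian Å."""
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        ca, cb, cg, sg = np.cos(al), np.cos(be), np.cos(ga), np.sin(ga)
        v = np.sqrt(1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg)
        return np.array(
            [
                [self.a, 0.0, 0.0],
                [self.b * cg, self.b * sg, 0.0],
                [self.c * cb, self.c * (ca - cb * cg) / sg, self.c * v / sg],
            ]
        )

    @property
    def volume(self) -> float:
        """Cell volume in Å³."""
        return float(abs(np.linalg.det(self.direct_basis)))


def reciprocal_basis(cell: UnitCell) -> np.ndarray:
    """Reciprocal basis (rows a*, b*, c* in Å⁻¹, 2π convention).

    Satisfies ``direct_basis @ reciprocal_basis.T = 2π·I`` to machine
    precision.
    """
    return 2.0 * np.pi * np.linalg.inv(cell.direct_basis).T


@dataclass
class BraggPeakList:
    """Reflections (h,k,l) with Cartesian q-vectors and intensities.

    ``hkl`` is (N,3) int, ``q_vec`` (N,3) float Å⁻¹, ``intensity`` (N,) ≥ 0.
    (0,0,0) is excluded and (h,k,l) are unique.
    """

    hkl: np.ndarray
    q_vec: np.ndarray
    intensity: np.ndarray
    q_max: float

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.q_vec = np.asarray(self.q_vec, dtype=float).reshape(-1, 3)
        self.intensity = np.asarray(self.intensity, dtype=float).reshape(-1)
        if len(self.intensity) != len(self.hkl) or len(self.q_vec) != len(self.hkl):
            raise ValueError("hkl, q_vec and intensity lengths differ")
        if len(self.hkl) and np.any(np.all(self.hkl == 0, axis=1)):
            raise ValueError("(0,0,0) is not a Bragg reflection")
        if len(self.hkl) != len(np.unique(self.hkl, axis=0)):
            raise ValueError("duplicate (h,k,l) entries")

    @property
    def q_mag(self) -> np.ndarray:
        return np.linalg.norm(self.q_vec, axis=1)

    def __len__(self) -> int:
        return len(self.hkl)

    def with_intensity(self, intensity: np.ndarray) -> "BraggPeakList":
        return BraggPeakList(self.hkl.copy(), self.q_vec.copy(),
                             np.asarray(intensity, float), self.q_max)


@dataclass
class AtomicModel:
    """Toy point-scatterer motif: fractional coordinates and positive weights."""

    fractional: np.ndarray
    weights: np.ndarray
    labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fractional = np.asarray(self.fractional, float).reshape(-1, 3) % 1.0
        self.weights = np.asarray(self.weights, float).reshape(-1)
        if len(self.fractional) == 0:
            raise ValueError("model needs at least one atom")
        if len(self.weights) != len(self.fractional):
            raise ValueError("weights/coordinates length mismatch")
        if np.any(self.weights <= 0):
            raise ValueError("scattering weights must be positive")
        if not self.labels:
            self.labels = [f"X{i+1}" for i in range(len(self.weights))]


def enumerate_hkl(cell: UnitCell, q_max: float, *, count_cap: int = 5_000_000) -> BraggPeakList:
    """All reflections with 0 < |h·a* + k·b* + l·c*| ≤ q_max (inclusive).

    Completeness: since h_i = (q · a_i)/2π, every qualifying triple satisfies
    |h_i| ≤ q_max·|a_i|/2π (Cauchy–Schwarz), so the searched index box is
    guaranteed sufficient.  Intensities are initialised to zero; systematic
    absences are not removed (they appear as zero intensities from the atomic
    model when one is applied).
    """
    if q_max <= 0:
        raise ValueError("q_max must be positive")
    rec = reciprocal_basis(cell)
    lens = np.linalg.norm(cell.direct_basis, axis=1)
    hmax = np.ceil(q_max * lens / (2.0 * np.pi)).astype(int)
    n_box = int(np.prod(2 * hmax.astype(np.int64) + 1))
    if n_box > count_cap:
        raise EnumerationSizeError(
            f"index box of {n_box} candidates exceeds cap {count_cap}"
        )
    axes = [np.arange(-m, m + 1) for m in hmax]
    hkl = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    q = hkl @ rec
    qmag = np.linalg.norm(q, axis=1)
    keep = (qmag <= q_max) & (qmag > 0)
    return BraggPeakList(hkl[keep], q[keep], np.zeros(keep.sum()), q_max)


def structure_factor_intensities(model: AtomicModel, peaks: BraggPeakList) -> BraggPeakList:
    """Bragg intensities |F_hkl|² for a toy point-atom model.

    F_hkl = Σ_j w_j exp(2πi (h x_j + k y_j + l z_j)); real weights guarantee
    Friedel symmetry I(hkl) = I(-h-k-l).
    """
    phase = 2.0 * np.pi * peaks.hkl.astype(float) @ model.fractional.T
    f = (model.weights[None, :] * np.exp(1j * phase)).sum(axis=1)
    return peaks.with_intensity(np.abs(f) ** 2)


def resolution_to_qmax(d: float) -> float:
    """q_max = 2π/d (d in Å, q in Å⁻¹)."""
    if d <= 0:
        raise ValueError("resolution must be positive")
    return 2.0 * np.pi / d


def qmax_to_resolution(q_max: float) -> float:
    """d = 2π/q_max, inverse of :func:`resolution_to_qmax`."""
    if q_max <= 0:
        raise ValueError("q_max must be positive")
    return 2.0 * np.pi / q_max


# ---------------------------------------------------------------------------
# text formats


def write_reflections(path: str | Path, peaks: BraggPeakList, header: str = "") -> None:
    """Whitespace-delimited reflection file: 'h k l intensity' per line."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"# q_max {peaks.q_max!r}\n")
        for (h, k, l), i in zip(peaks.hkl, peaks.intensity):
            fh.write(f"{h} {k} {l} {i:.10g}\n")


def read_reflections(path: str | Path, cell: UnitCell, q_max: float | None = None) -> BraggPeakList:
    """Read 'h k l intensity' lines; q-vectors are rebuilt from the cell."""
    hkl, inten = [], []
    stored_qmax = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                toks = line[1:].split()
                if len(toks) == 2 and toks[0] == "q_max":
                    stored_qmax = float(toks[1])
                continue
            toks = line.split()
            hkl.append([int(toks[0]), int(toks[1]), int(toks[2])])
            inten.append(float(toks[3]) if len(toks) > 3 else 0.0)
    hkl_arr = np.asarray(hkl, int).reshape(-1, 3)
    q = hkl_arr @ reciprocal_basis(cell)
    if q_max is None:
        q_max = stored_qmax if stored_qmax is not None else float(
            np.linalg.norm(q, axis=1).max(initial=0.0)
        )
    return BraggPeakList(hkl_arr, q, np.asarray(inten, float), q_max)


def read_cell_cif(path: str | Path) -> UnitCell:
    """Read a unit cell from the core CIF cell tags."""
    import gemmi

    doc = gemmi.cif.read_file(str(path))
    block = doc.sole_block()

    def val(tag: str) -> float:
        raw = block.find_value(tag)
        if raw is None:
            raise InvalidCellError(f"missing CIF tag {tag}")
        return float(gemmi.cif.as_number(raw))

    return UnitCell(
        val("_cell_length_a"), val("_cell_length_b"), val("_cell_length_c"),
        val("_cell_angle_alpha"), val("_cell_angle_beta"), val("_cell_angle_gamma"),
    )
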