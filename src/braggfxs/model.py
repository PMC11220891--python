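"""Model/Results interface for Bragg-intensity recovery.

:class:`BraggRecovery` is constructed from the measured data (an
η-parametrised correlation volume plus the unit cell) and owns everything
derived from them: the enumerated reflection list, the harmonic order
matrices extracted by Legendre pseudo-inversion, the eigenbasis of the
modulus constraint and the Bragg support mask.  :meth:`BraggRecovery.fit`
runs an iterative recipe from a random start and returns a
:class:`RecoveryResults` carrying the recovered intensity volume, per-peak
intensities, the per-iteration R-factor trace and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constraints import ModulusConstraint, SupportConstraint, build_support_mask
from .correlation import CorrelationVolume
from .geometry import DEFAULT_ORIENTATION
from .harmonics import SphericalGrid, b_from_correlation, truncate_b
from .iterate import Recipe, RunState, random_init, run_recipe
from .lattice import BraggPeakList, UnitCell, enumerate_hkl
from .metrics import extract_peak_intensities, r_factor, r_iso

__all__ = ["BraggRecovery", "RecoveryResults"]


class BraggRecovery:
    """Iterative-projection recovery of Bragg intensities from a correlation
    volume and known unit-cell parameters.

    Parameters
    ----------
    correlation
        η-parametrised C(q1,q2,η); its n_q and q_max fix the radial grid.
    cell
        Unit cell whose reciprocal lattice supplies the Bragg support.
    n_theta
        Angular sampling of the intensity iterate (n_φ = 2n_θ).
    l_cut
        Harmonic order matrices at l ≥ l_cut are zeroed (None keeps all
        n_θ/2 degrees).
    support_width
        Odd block width (voxels) of the per-peak support volumes.
    beta
        HIO feedback parameter.
    from_histogram
        Treat the correlation as a raw pair-product histogram and remove the
        analytic 2πΔη factor when extracting B (the convention produced by
        :func:`braggfxs.correlation.correlate_3d`).
    """

    def __init__(
        self,
        correlation: CorrelationVolume,
        cell: UnitCell,
        *,
        n_theta: int = 32,
        l_cut: int | None = None,
        support_width: int = 5,
        beta: float = 0.9,
        rotation=DEFAULT_ORIENTATION,
        from_histogram: bool = True,
        rcond: float = 1e-10,
        reference: np.ndarray | None = None,
    ):
        if correlation.angular_coordinate != "eta":
            raise ValueError("correlation must be η-parametrised")
        self.correlation = correlation
        self.cell = cell
        self.grid = SphericalGrid(correlation.n_q, n_theta, correlation.q_max)
        self.l_cut = l_cut
        self.support_width = support_width
        self.beta = beta
        self.rotation = rotation
        self.reference = None if reference is None else np.asarray(reference, float)

        self.peaks: BraggPeakList = enumerate_hkl(cell, correlation.q_max)
        b = b_from_correlation(
            correlation, self.grid.n_l, rcond=rcond, from_histogram=from_histogram
        )
        if l_cut is not None:
            b = truncate_b(b, l_cut)
        self.b = b
        self.modulus = ModulusConstraint.from_b(b)
        self.mask = build_support_mask(
            self.peaks, self.grid, support_width, rotation=rotation
        )
        self.support = SupportConstraint(self.mask)

    @classmethod
    def from_bundle(cls, bundle, *, l_cut: int | None = None, beta: float = 0.9,
                    **kw) -> "BraggRecovery":
        """Build a model from a synthetic fixture bundle, using its true peak
        intensities as the R-factor reference."""
        return cls(
            bundle.correlation,
            bundle.cell,
            n_theta=bundle.grid.n_theta,
            l_cut=l_cut,
            support_width=bundle.support_width,
            beta=beta,
            rotation=bundle.rotation,
            reference=bundle.peaks.intensity,
            **kw,
        )

    # -- fitting ----------------------------------------------------------

    def extract(self, intensity) -> np.ndarray:
        """Solid-angle-integrated per-peak intensities of an iterate."""
        return extract_peak_intensities(
            intensity, self.peaks, self.support_width,
            rotation=self.rotation, mode="integrate",
        )

    def fit(self, recipe: str | Recipe = "120HIO", seed: int = 0) -> "RecoveryResults":
        """Run a recipe from a uniform random start; deterministic per seed."""
        if isinstance(recipe, str):
            recipe = Recipe.parse(recipe, beta=self.beta)
        state = RunState(random_init(self.grid, seed), seed=seed)
        initial_r = None
        if self.reference is not None:
            start = self.support(state.intensity)
            initial_r = r_factor(self.extract(start), self.reference)
        state = run_recipe(
            state, recipe, self.modulus, self.support,
            reference=self.reference,
            extract=self.extract if self.reference is not None else None,
        )
        final = self.support(state.intensity)
        recovered = self.extract(final)
        return RecoveryResults(
            model=self,
            state=state,
            recipe=recipe,
            seed=seed,
            peak_intensities=recovered,
            initial_r=initial_r,
        )

    def fit_multistart(self, seeds, recipe: str | Recipe = "120HIO") -> list["RecoveryResults"]:
        return [self.fit(recipe, seed=s) for s in seeds]


@dataclass
class RecoveryResults:
    """Recovered intensities plus convergence diagnostics of one run."""

    model: BraggRecovery
    state: RunState
    recipe: Recipe
    seed: int
    peak_intensities: np.ndarray
    initial_r: float | None = None
    _: dict = field(default_factory=dict, repr=False)

    @property
    def intensity(self):
        """Final support-projected intensity volume."""
        return self.model.support(self.state.intensity)

    @property
    def r_trace(self) -> np.ndarray:
        return np.asarray(self.state.r_trace)

    @property
    def final_r(self) -> float | None:
        return self.r_trace[-1] if len(self.state.r_trace) else None

    @property
    def recovered_peaks(self) -> BraggPeakList:
        return self.model.peaks.with_intensity(self.peak_intensities)

    def r_iso_with(self, other: "RecoveryResults") -> float:
        """R_iso between this run's and another run's recovered intensities."""
        return r_iso(self.peak_intensities, other.peak_intensities)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Bragg-intensity recovery",
            "========================",
            f"cell                 a={m.cell.a:.4f} b={m.cell.b:.4f} c={m.cell.c:.4f} Å, "
            f"α={m.cell.alpha:.3f} β={m.cell.beta:.3f} γ={m.cell.gamma:.3f}°",
            f"q_max                {m.grid.q_max:.4g} Å⁻¹   reflections: {len(m.peaks)}",
            f"grid                 n_q={m.grid.n_q} n_θ={m.grid.n_theta} n_φ={m.grid.n_phi}",
            f"harmonic cutoff      l_cut={m.l_cut if m.l_cut is not None else m.grid.n_l}",
            f"support              width {m.support_width} voxels, "
            f"{m.mask.overlap_pairs} overlapping peak pairs",
            f"recipe               {', '.join(f'{c}{s}' for s, c in self.recipe.steps[:6])}"
            f"{' …' if len(self.recipe.steps) > 6 else ''} "
            f"({self.recipe.total_iterations} iterations, β={self.recipe.beta})",
            f"seed                 {self.seed}",
        ]
        if self.initial_r is not None:
            lines.append(f"initial R            {self.initial_r:.4f}")
        if self.final_r is not None:
            lines.append(f"final R              {self.final_r:.4f}")
        return "\n".join(lines)
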