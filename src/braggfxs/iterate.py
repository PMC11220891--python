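"""Iterative schemes (ER, HIO), recipe parsing and per-iteration telemetry.

ER composes the projections directly, I' = P_s(P_m(I)).  HIO keeps the
modulus-projected value wherever it already satisfies the combined
support+positivity constraint and applies negative feedback
I − β·P_m(I) elsewhere.  Recipes are comma-separated ``<N><SCHEME>`` tokens
with an optional ``xK`` repetition suffix applying to the whole list, e.g.
``"20HIO,2ER x5"`` = 110 iterations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .harmonics import SphericalGrid, SphericalIntensity

__all__ = ["Recipe", "RunState", "random_init", "er_step", "hio_step", "run_recipe"]

_TOKEN = re.compile(r"^(\d+)\s*(ER|HIO)$", re.IGNORECASE)


@dataclass(frozen=True)
class Recipe:
    """Ordered (scheme, count) steps with HIO feedback parameter β."""

    steps: tuple[tuple[str, int], ...]
    beta: float = 0.9

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("recipe has no steps")
        for scheme, count in self.steps:
            if scheme not in ("ER", "HIO"):
                raise ValueError(f"unknown scheme {scheme!r}")
            if count <= 0:
                raise ValueError("iteration counts must be positive")
        if not 0.0 < self.beta < 2.0:
            raise ValueError("beta must lie in (0, 2)")

    @property
    def total_iterations(self) -> int:
        return sum(c for _, c in self.steps)

    def schedule(self) -> list[str]:
        """Flat per-iteration scheme list."""
        out: list[str] = []
        for scheme, count in self.steps:
            out.extend([scheme] * count)
        return out

    @classmethod
    def parse(cls, text: str, beta: float = 0.9) -> "Recipe":
        text = text.strip()
        m = re.match(r"^(.*?)(?:\s*[xX]\s*(\d+))?$", text)
        body, reps = m.group(1), int(m.group(2) or 1)
        steps: list[tuple[str, int]] = []
        for tok in body.split(","):
            tok = tok.strip()
            if not tok:
                continue
            tm = _TOKEN.match(tok)
            if tm is None:
                raise ValueError(f"cannot parse recipe token {tok!r}")
            steps.append((tm.group(2).upper(), int(tm.group(1))))
        if not steps:
            raise ValueError(f"empty recipe {text!r}")
        return cls(tuple(steps * reps), beta)


@dataclass
class RunState:
    """Iterate plus telemetry of a recovery run."""

    intensity: SphericalIntensity
    iteration: int = 0
    seed: int | None = None
    r_trace: list[float] = field(default_factory=list)
    scheme_trace: list[str] = field(default_factory=list)


def random_init(grid: SphericalGrid, seed: int) -> SphericalIntensity:
    """I.i.d. uniform start in [−1, 1], reproducible per seed."""
    rng = np.random.default_rng(seed)
    return SphericalIntensity(rng.uniform(-1.0, 1.0, size=grid.shape), grid)


def er_step(intensity: SphericalIntensity, p_m, p_s) -> SphericalIntensity:
    """Error reduction: I' = P_s(P_m(I))."""
    return p_s(p_m(intensity))


def hio_step(intensity: SphericalIntensity, p_m, mask, beta: float) -> SphericalIntensity:
    """Hybrid input–output update.

    Voxels where the modulus-projected value already satisfies the support
    and positivity constraints (inside the mask and non-negative) keep the
    P_m output; all others receive the feedback value I − β·P_m(I).
    """
    pm = p_m(intensity)
    good = (np.asarray(mask.values, bool)) & (pm.values >= 0.0)
    out = np.where(good, pm.values, intensity.values - beta * pm.values)
    return SphericalIntensity(out, intensity.grid)


def run_recipe(
    state: RunState,
    recipe: Recipe,
    p_m,
    support,
    *,
    reference=None,
    extract=None,
) -> RunState:
    """Execute a recipe, recording the R factor against ``reference`` (a peak
    intensity array) every iteration when provided.

    ``support`` is the SupportConstraint (its mask drives the HIO region);
    ``extract`` maps a support-projected iterate to per-peak intensities.
    Deterministic given the starting state.
    """
    from .metrics import r_factor

    mask = support.mask
    for scheme in recipe.schedule():
        if scheme == "ER":
            state.intensity = er_step(state.intensity, p_m, support)
        else:
            state.intensity = hio_step(state.intensity, p_m, mask, recipe.beta)
        state.iteration += 1
        state.scheme_trace.append(scheme)
        if reference is not None and extract is not None:
            from .constraints import support_project

            constrained = support_project(state.intensity, mask)
            state.r_trace.append(r_factor(extract(constrained), reference))
    return state
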